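"""Beta-mixture quantile (BMIQ) normalization of probe-design bias.

Infinium arrays mix two probe chemistries whose beta-value
distributions differ: type-II probes are compressed toward 0.5
relative to type-I probes. BMIQ fits a three-state beta mixture
(unmethylated / hemi-methylated / methylated) to each design class and
quantile-maps the type-II U- and M-state values onto the corresponding
type-I mixture components; hemi-methylated values are carried across by
a linear (dilation) map between the transformed state boundaries.
Type-I values are returned unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats


class BMIQError(RuntimeError):
    """Degenerate mixture fit (empty or collapsed state)."""


@dataclass
class BetaMixture:
    """Three-state beta mixture, components sorted by mean."""

    a: np.ndarray  # shape (3,)
    b: np.ndarray
    w: np.ndarray
    loglik: float
    n_iter: int
    converged: bool

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        logp = (
            np.log(self.w)[None, :]
            + (self.a - 1.0)[None, :] * np.log(x)[:, None]
            + (self.b - 1.0)[None, :] * np.log1p(-x)[:, None]
            - special.betaln(self.a, self.b)[None, :]
        )
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def classify(self, x: np.ndarray) -> np.ndarray:
        """Hard state labels 0=U, 1=H, 2=M by maximum responsibility."""
        return np.argmax(self.responsibilities(x), axis=1)


def _moment_match(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted method-of-moments estimate of beta shape parameters."""
    wsum = w.sum()
    m = float((w * x).sum() / wsum)
    v = float((w * (x - m) ** 2).sum() / wsum)
    v = max(v, 1e-8)
    m = min(max(m, 1e-4), 1 - 1e-4)
    common = m * (1 - m) / v - 1.0
    common = max(common, 1e-2)
    return m * common, (1 - m) * common


def _weighted_beta_mle(
    x: np.ndarray, w: np.ndarray, a0: float, b0: float, n_newton: int = 25
) -> tuple[float, float]:
    """Weighted maximum-likelihood beta shapes by Newton iteration.

    Solves digamma(a) - digamma(a+b) = mean_w(log x) and the mirrored
    equation for b, starting from ``(a0, b0)`` (typically the moment
    estimate). Falls back to the start value if the iteration leaves
    the feasible region.
    """
    wsum = w.sum()
    t1 = float((w * np.log(x)).sum() / wsum)
    t2 = float((w * np.log1p(-x)).sum() / wsum)
    a, b = a0, b0
    for _ in range(n_newton):
        dga, dgb, dgab = special.digamma((a, b, a + b))
        f1 = dga - dgab - t1
        f2 = dgb - dgab - t2
        tga, tgb, tgab = special.polygamma(1, (a, b, a + b))
        j11, j22, j12 = tga - tgab, tgb - tgab, -tgab
        det = j11 * j22 - j12 * j12
        if not np.isfinite(det) or det <= 0:
            return a0, b0
        da = (j22 * f1 - j12 * f2) / det
        db = (j11 * f2 - j12 * f1) / det
        step = 1.0
        while (a - step * da <= 0 or b - step * db <= 0) and step > 1e-4:
            step /= 2.0
        a, b = a - step * da, b - step * db
        if max(abs(da), abs(db)) < 1e-10 * (1.0 + max(a, b)):
            break
    if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
        return a0, b0
    return float(a), float(b)


def fit_beta_mixture(
    x: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-6,
    eps: float = 1e-6,
) -> BetaMixture:
    """EM fit of a 3-state beta mixture.

    Initialization splits the beta scale at 1/3 and 2/3 (falling back
    to data quantiles when a band is near-empty) with moment-matched
    shapes; the M-step is the weighted
    maximum-likelihood update per component (Newton on the digamma
    equations, warm-started from the moment estimate), so the
    log-likelihood ascends monotonically.
    Convergence is declared on a relative log-likelihood change below
    ``tol``; hitting ``max_iter`` first emits a warning with
    diagnostics. A component whose weight collapses raises
    :class:`BMIQError`.
    """
    x = np.clip(np.asarray(x, dtype=float), eps, 1 - eps)
    if x.size < 30:
        raise BMIQError(f"too few values ({x.size}) for a 3-state fit")
    labels = np.digitize(x, [1 / 3, 2 / 3])
    if min(np.bincount(labels, minlength=3)) < 3:
        q1, q2 = np.quantile(x, [1 / 3, 2 / 3])
        labels = np.digitize(x, [q1, q2])
    a = np.empty(3)
    b = np.empty(3)
    w = np.empty(3)
    for s in range(3):
        mask = labels == s
        if mask.sum() < 3:
            raise BMIQError("degenerate initialization: empty state")
        a[s], b[s] = _moment_match(x[mask], np.ones(mask.sum()))
        w[s] = mask.mean()
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logp = (
            np.log(w)[None, :]
            + (a - 1.0)[None, :] * np.log(x)[:, None]
            + (b - 1.0)[None, :] * np.log1p(-x)[:, None]
            - special.betaln(a, b)[None, :]
        )
        mx = logp.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(logp - mx).sum(axis=1))
        loglik = float(lse.sum())
        resp = np.exp(logp - lse[:, None])
        w = resp.mean(axis=0)
        if np.any(w < 1e-4):
            raise BMIQError(f"mixture component collapsed (weights {w})")
        for s in range(3):
            a_mom, b_mom = _moment_match(x, resp[:, s])
            a[s], b[s] = _weighted_beta_mle(x, resp[:, s], a_mom, b_mom)
        if np.isfinite(prev) and abs(loglik - prev) <= tol * (abs(prev) + 1.0):
            converged = True
            break
        prev = loglik
    if not converged:
        warnings.warn(
            f"beta-mixture EM did not converge in {max_iter} iterations "
            f"(last log-likelihood {loglik:.6g})"
        )
    order = np.argsort(a / (a + b))
    return BetaMixture(a=a[order], b=b[order], w=w[order], loglik=loglik,
                       n_iter=it, converged=converged)


def bmiq_normalize(
    beta_sample: np.ndarray,
    design_class: np.ndarray,
    eps: float = 1e-6,
    max_fit_points: int = 5000,
    rng_seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> np.ndarray:
    """Normalize one sample's type-II betas onto the type-I scale.

    Both design classes must be present. Mixtures are fitted on at most
    ``max_fit_points`` values per class (deterministic subsample) and
    then applied to all probes. Returns a vector with type-I values
    unchanged and type-II values mapped; output clipped to [0, 1].
    """
    x = np.asarray(beta_sample, dtype=float)
    cls = np.asarray(design_class)
    is1 = cls == "I"
    is2 = cls == "II"
    if not (is1.any() and is2.any()):
        raise ValueError("both design classes must be present")
    xc = np.clip(x, eps, 1 - eps)

    rng = np.random.default_rng(rng_seed)

    def fit_subset(values: np.ndarray) -> BetaMixture:
        if values.size > max_fit_points:
            values = rng.choice(values, size=max_fit_points, replace=False)
        return fit_beta_mixture(values, max_iter=max_iter, tol=tol, eps=eps)

    mix1 = fit_subset(xc[is1])
    mix2 = fit_subset(xc[is2])

    x2 = xc[is2]
    state = mix2.classify(x2)
    out2 = x2.copy()

    # U state: lower-tail quantile map II-U -> I-U
    u = state == 0
    if u.any():
        p = stats.beta.cdf(x2[u], mix2.a[0], mix2.b[0])
        out2[u] = stats.beta.ppf(p, mix1.a[0], mix1.b[0])
    # M state: upper-tail quantile map II-M -> I-M
    m = state == 2
    if m.any():
        p = stats.beta.sf(x2[m], mix2.a[2], mix2.b[2])
        out2[m] = stats.beta.isf(p, mix1.a[2], mix1.b[2])
    # H state: dilation between the transformed U max and M min
    h = state == 1
    if h.any():
        h_lo, h_hi = x2[h].min(), x2[h].max()
        lo_target = out2[u].max() if u.any() else h_lo
        hi_target = out2[m].min() if m.any() else h_hi
        if h_hi > h_lo and hi_target > lo_target:
            out2[h] = lo_target + (x2[h] - h_lo) * (hi_target - lo_target) / (h_hi - h_lo)
        # else: leave H values untouched (degenerate span)

    out = x.astype(float).copy()
    out[is2] = np.clip(out2, 0.0, 1.0)
    return out


def bmiq_matrix(beta, annotation, **kwargs):
    """Apply :func:`bmiq_normalize` column-by-column to a beta DataFrame.

    Missing entries pass through unchanged (the mixture is fitted on
    observed values only).
    """
    cls = annotation.loc[beta.index, "design_class"].to_numpy()
    out = beta.copy()
    for col in beta.columns:
        x = beta[col].to_numpy(dtype=float)
        obs = ~np.isnan(x)
        normalized = bmiq_normalize(x[obs], cls[obs], **kwargs)
        y = x.copy()
        y[obs] = normalized
        out[col] = y
    return out
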