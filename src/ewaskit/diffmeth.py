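"""Differential methylation via moderated linear models.

Per-feature (probe or promoter) ordinary least squares on beta values
under an intercept-free design, followed by empirical-Bayes variance
moderation: residual variances are shrunk toward a pooled prior whose
degrees of freedom and scale are estimated by moment matching on
log s^2 (digamma/trigamma matching of a scaled-F model). Moderated
t-statistics, two-sided p-values, signed-z ranking statistics and
Bonferroni significance calls follow.

Designs
-------
paired
    ``~ 0 + time + subject + covariates`` — both time-level columns,
    subject indicator block (reference = first subject by sort order),
    contrast post - pre.
single
    ``~ 0 + treatment + covariates`` — both treatment-level columns,
    contrast treated - untreated. Categorical covariates expand to
    indicators against a documented reference level (earliest batch,
    majority ethnicity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats


@dataclass
class DesignMatrix:
    X: pd.DataFrame  # samples x columns
    contrast: pd.Series  # length = columns
    roles: dict[str, str] = field(default_factory=dict)

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.X.to_numpy()))


@dataclass
class FeatureFits:
    feature_ids: pd.Index
    effect: np.ndarray  # contrast coefficient per feature
    stdev_unscaled: float  # sqrt(c' (X'X)^- c), shared across features
    s2: np.ndarray  # residual variance per feature
    df_residual: int
    coefficients: np.ndarray | None = None  # features x columns


def _expand_covariates(sheet: pd.DataFrame, adjust, X_cols: dict) -> None:
    """Append covariate columns to ``X_cols`` (categoricals to indicators)."""
    for cov in adjust:
        col = sheet[cov]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            X_cols[cov] = col.to_numpy(dtype=float)
        else:
            levels = col.astype(str)
            counts = levels.value_counts()
            # reference level: earliest by sort order for batch-like codes,
            # majority level otherwise
            ref = sorted(counts.index)[0] if cov == "batch" else counts.idxmax()
            others = [l for l in sorted(counts.index) if l != ref]
            if not others:
                warnings.warn(f"covariate '{cov}' has a single level; dropped")
                continue
            for lev in others:
                X_cols[f"{cov}[{lev}]"] = (levels == lev).to_numpy(dtype=float)


def build_design(
    sheet: pd.DataFrame,
    mode: str,
    adjust: list[str] | None = None,
    extra_numeric: pd.DataFrame | None = None,
) -> DesignMatrix:
    """Construct the intercept-free design and its tested contrast.

    ``extra_numeric`` columns (e.g. inferred cell fractions or immune
    content) are appended as numeric covariates. Raises on unpaired
    subjects (paired mode) or collinear covariates, naming the
    offending columns.
    """
    adjust = list(adjust or [])
    X_cols: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    if mode == "paired":
        counts = sheet.groupby("subject_id")["timepoint"].agg(["size", "nunique"])
        bad = counts[(counts["size"] != 2) | (counts["nunique"] != 2)]
        if len(bad):
            raise ValueError(f"unpaired subjects in paired mode: {list(bad.index)[:5]}")
        tp = sheet["timepoint"].astype(str)
        X_cols["time[pre]"] = (tp == "pre").to_numpy(dtype=float)
        X_cols["time[post]"] = (tp == "post").to_numpy(dtype=float)
        subjects = sorted(sheet["subject_id"].unique())
        for s in subjects[1:]:  # first subject is the reference
            X_cols[f"subject[{s}]"] = (sheet["subject_id"] == s).to_numpy(dtype=float)
        contrast_pos, contrast_neg = "time[post]", "time[pre]"
        roles.update({"time[pre]": "treatment", "time[post]": "treatment"})
    elif mode == "single":
        tr = sheet["treated"].astype(bool)
        X_cols["chemo[no]"] = (~tr).to_numpy(dtype=float)
        X_cols["chemo[yes]"] = tr.to_numpy(dtype=float)
        contrast_pos, contrast_neg = "chemo[yes]", "chemo[no]"
        roles.update({"chemo[no]": "treatment", "chemo[yes]": "treatment"})
    else:
        raise ValueError("mode must be 'paired' or 'single'")

    _expand_covariates(sheet, adjust, X_cols)
    if extra_numeric is not None:
        for c in extra_numeric.columns:
            X_cols[str(c)] = extra_numeric[c].to_numpy(dtype=float)

    X = pd.DataFrame(X_cols, index=sheet.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        offenders = _find_collinear(X)
        raise ValueError(f"collinear design columns: {offenders}")
    contrast = pd.Series(0.0, index=X.columns)
    contrast[contrast_pos] = 1.0
    contrast[contrast_neg] = -1.0
    return DesignMatrix(X=X, contrast=contrast, roles=roles)


def _find_collinear(X: pd.DataFrame) -> list[str]:
    """Greedily identify columns that reduce matrix rank."""
    cols: list[str] = []
    kept: list[str] = []
    for c in X.columns:
        trial = X[kept + [c]].to_numpy()
        if np.linalg.matrix_rank(trial) < len(kept) + 1:
            cols.append(c)
        else:
            kept.append(c)
    return cols


def fit_feature_models(beta: pd.DataFrame, design: DesignMatrix) -> FeatureFits:
    """Per-feature OLS under the shared design.

    Features are rows of ``beta``; samples must match the design index.
    Returns contrast effects, the shared unscaled standard deviation of
    the contrast, per-feature residual variances and residual df.
    """
    X = design.X.loc[beta.columns].to_numpy(dtype=float)
    Y = beta.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("beta matrix must be complete")
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    df = n - rank
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")
    pinv = np.linalg.pinv(X)
    B = Y @ pinv.T  # features x columns
    resid = Y - B @ X.T
    s2 = (resid**2).sum(axis=1) / df
    c = design.contrast.to_numpy(dtype=float)
    xtx_inv = pinv @ pinv.T  # (X'X)^- for full-rank X
    su = float(np.sqrt(c @ xtx_inv @ c))
    effect = B @ c
    return FeatureFits(
        feature_ids=beta.index,
        effect=effect,
        stdev_unscaled=su,
        s2=s2,
        df_residual=int(df),
        coefficients=B,
    )


def trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        step = (tri - y) / special.polygamma(2, x)
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < 1e-10 * (abs(x) + 1.0):
            x = x_new
            break
        x = x_new
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-matched prior (d0, s0^2) for the scaled-F variance model.

    Matches the mean and variance of e = log(s^2) - digamma(df/2) +
    log(df/2) against the scaled-F implied moments: Var(e) in excess of
    trigamma(df/2) determines d0 via trigamma inversion; the mean fixes
    s0^2. Zero variances are excluded by the caller.
    """
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) if len(e) > 1 else 0.0
    excess = evar - float(special.polygamma(1, df / 2.0))
    if excess > 0:
        d0 = 2.0 * trigamma_inverse(excess)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess dispersion: fully pooled prior at the mean variance
        d0 = np.inf
        s0_2 = float(np.mean(s2))
    return d0, s0_2


def ebayes_moderate(fits: FeatureFits, alpha: float | None = None) -> pd.DataFrame:
    """Empirical-Bayes moderated tests for the fitted contrast.

    Returns a DataFrame with columns ``effect, stderr, t, df_total, p,
    z, s2_post``. The ranking statistic z is the signed normal quantile
    of the two-sided p: z = sign(effect) * Phi^-1(1 - p/2). Features
    with zero residual variance are excluded from prior estimation and
    assigned the prior variance.
    """
    s2 = fits.s2
    df = fits.df_residual
    positive = s2 > 0
    if positive.sum() < 10:
        warnings.warn("fewer than 10 informative features; using unmoderated t")
        d0, s0_2 = 0.0, 0.0
        s2_post = s2.copy()
        df_total = float(df)
    else:
        d0, s0_2 = estimate_variance_prior(s2[positive], df)
        if not np.isfinite(s0_2) or s0_2 <= 0:
            warnings.warn("non-finite variance prior; falling back to unmoderated t")
            d0, s0_2 = 0.0, 0.0
        # total df capped at the pooled residual df, as in the moderated-t model
        df_pooled = float(len(s2) * df)
        if np.isfinite(d0):
            s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
            df_total = min(float(df + d0), df_pooled)
        else:
            s2_post = np.full_like(s2, s0_2)
            df_total = df_pooled
        if d0 > 0 and s0_2 > 0:
            s2_post = np.where(positive, s2_post, s0_2)
    stderr = fits.stdev_unscaled * np.sqrt(s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(stderr > 0, fits.effect / stderr, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 1e-300, 1.0)
    z = np.sign(fits.effect) * stats.norm.isf(p / 2.0)
    out = pd.DataFrame(
        {
            "effect": fits.effect,
            "stderr": stderr,
            "t": t,
            "df_total": df_total,
            "p": p,
            "z": z,
            "s2_post": s2_post,
        },
        index=fits.feature_ids,
    )
    out.index.name = "feature_id"
    out.attrs["d0"] = d0
    out.attrs["s0_2"] = s0_2
    if alpha is not None:
        out["significant"] = out["p"] < alpha
    return out


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / n."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def build_region_map(annotation: pd.DataFrame) -> pd.DataFrame:
    """Promoter membership table (promoter_id, gene_id, probe order)."""
    ann = annotation[annotation["promoter_id"] != ""]
    return ann[["promoter_id", "gene_id"]]


def regions_from_tss(
    annotation: pd.DataFrame,
    tss: pd.DataFrame,
    upstream: int = 1500,
    downstream: int = 500,
) -> pd.DataFrame:
    """Assign probes to promoters from TSS coordinates.

    ``tss`` needs columns ``chrom, pos, strand, promoter_id, gene_id``;
    a probe belongs to a promoter when its position falls within
    [pos - upstream, pos + downstream) on the + strand (mirrored on -).
    First matching promoter wins for probes hit by several.
    """
    assign_prom = pd.Series("", index=annotation.index, dtype=object)
    assign_gene = pd.Series("", index=annotation.index, dtype=object)
    for _, row in tss.iterrows():
        if row.get("strand", "+") == "-":
            lo, hi = row["pos"] - downstream, row["pos"] + upstream
        else:
            lo, hi = row["pos"] - upstream, row["pos"] + downstream
        hit = (
            (annotation["chrom"] == row["chrom"])
            & (annotation["start"] >= lo)
            & (annotation["start"] < hi)
            & (assign_prom == "")
        )
        assign_prom[hit] = row["promoter_id"]
        assign_gene[hit] = row["gene_id"]
    out = pd.DataFrame({"promoter_id": assign_prom, "gene_id": assign_gene})
    return out[out["promoter_id"] != ""]


def aggregate_promoters(beta: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Promoter-level matrix: mean of member probes' betas per sample.

    Promoters whose probes were all filtered out are dropped. ``regions``
    is a probe-indexed frame with a ``promoter_id`` column (see
    :func:`build_region_map`).
    """
    shared = regions.index.intersection(beta.index)
    if len(shared) == 0:
        raise ValueError("no region probes present in the beta matrix")
    groups = regions.loc[shared, "promoter_id"]
    agg = beta.loc[shared].groupby(groups).mean()
    agg.index.name = "promoter_id"
    return agg


def call_significant(results: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Flag features with p strictly below the threshold."""
    out = results.copy()
    out["significant"] = out["p"] < threshold
    return out


def intersect_significant(result_sets: list[pd.DataFrame]) -> pd.Index:
    """Features significant with sign-concordant effects in every set."""
    if not result_sets:
        return pd.Index([])
    common: pd.Index | None = None
    for res in result_sets:
        if "significant" not in res.columns:
            raise ValueError("call_significant must be applied first")
        sig = res.index[res["significant"]]
        common = sig if common is None else common.intersection(sig)
    keep = []
    for f in common:
        signs = {np.sign(res.at[f, "effect"]) for res in result_sets}
        if len(signs) == 1 and 0.0 not in signs:
            keep.append(f)
    return pd.Index(keep)
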