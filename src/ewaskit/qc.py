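"""Quality control, filtering, imputation and global-methylation summary.

The stage order mirrors standard array processing: detection-p based
Greedycut removal of unreliable samples/probes, probe-design (BMIQ)
normalization (see :mod:`ewaskit.bmiq`), annotation/variability filters,
kNN imputation of the remaining missing entries, and the per-sample
genome-wide methylation summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class QCReport:
    """Per-axis removal log with reason codes.

    Conservation: every input probe/sample ends up exactly once as
    retained or removed.
    """

    removed_probes: dict[str, str] = field(default_factory=dict)
    removed_samples: dict[str, str] = field(default_factory=dict)
    retained_probes: list[str] = field(default_factory=list)
    retained_samples: list[str] = field(default_factory=list)

    def add_probe_removals(self, ids, reason: str) -> None:
        for i in ids:
            self.removed_probes.setdefault(i, reason)

    def add_sample_removals(self, ids, reason: str) -> None:
        for i in ids:
            self.removed_samples.setdefault(i, reason)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for reason in self.removed_probes.values():
            out[f"probes_removed:{reason}"] = out.get(f"probes_removed:{reason}", 0) + 1
        for reason in self.removed_samples.values():
            out[f"samples_removed:{reason}"] = out.get(f"samples_removed:{reason}", 0) + 1
        out["probes_retained"] = len(self.retained_probes)
        out["samples_retained"] = len(self.retained_samples)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [("probe", i, r) for i, r in self.removed_probes.items()]
        rows += [("sample", i, r) for i, r in self.removed_samples.items()]
        return pd.DataFrame(rows, columns=["axis", "id", "reason"])


def greedycut_filter(
    detection_p: pd.DataFrame,
    alpha: float = 0.01,
    stop_frac: float = 0.05,
) -> tuple[list[str], list[str], QCReport]:
    """Iterative removal of unreliable probes/samples by detection p.

    At each step the row (probe) or column (sample) with the largest
    fraction of entries failing ``p > alpha`` is removed — rows win
    ties — until no remaining row or column fails more than
    ``stop_frac`` of its entries. Sporadic failures that survive are
    expected to be masked and imputed downstream (see
    :func:`mask_failed_entries`).
    """
    if detection_p.size == 0:
        raise ValueError("empty detection-p matrix")
    fail = (detection_p.to_numpy() > alpha)
    rows = np.ones(fail.shape[0], dtype=bool)
    cols = np.ones(fail.shape[1], dtype=bool)
    report = QCReport()
    while rows.any() and cols.any():
        sub = fail[np.ix_(rows, cols)]
        row_frac = sub.mean(axis=1)
        col_frac = sub.mean(axis=0)
        r_best = int(np.argmax(row_frac))
        c_best = int(np.argmax(col_frac))
        worst = max(row_frac[r_best], col_frac[c_best])
        if worst <= stop_frac:
            break
        if row_frac[r_best] >= col_frac[c_best]:  # rows removed on ties
            idx = np.flatnonzero(rows)[r_best]
            rows[idx] = False
            report.removed_probes[detection_p.index[idx]] = "greedycut"
        else:
            idx = np.flatnonzero(cols)[c_best]
            cols[idx] = False
            report.removed_samples[detection_p.columns[idx]] = "greedycut"
    report.retained_probes = list(detection_p.index[rows])
    report.retained_samples = list(detection_p.columns[cols])
    return report.retained_probes, report.retained_samples, report


def mask_failed_entries(
    beta: pd.DataFrame, detection_p: pd.DataFrame, alpha: float = 0.01
) -> pd.DataFrame:
    """Set individual entries with detection p > alpha to missing."""
    detp = detection_p.loc[beta.index, beta.columns]
    out = beta.where(~(detp > alpha))
    return out


DEFAULT_DROP_CONTEXTS = frozenset({"CC", "CAG", "CAH", "CTG", "CTH", "Other"})


def filter_probes(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    sd_min: float = 0.005,
    drop_contexts=DEFAULT_DROP_CONTEXTS,
    drop_snp: bool = True,
    drop_cross_reactive: bool = True,
    drop_chrY: bool = True,
    report: QCReport | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Annotation and variability probe filters (set-intersection semantics).

    Removes non-CpG-context probes, SNP-overlapping and cross-reactive
    probes, chromosome-Y probes, and probes whose standard deviation
    across samples is strictly below ``sd_min``. Each removed probe is
    logged under the first matching criterion, but membership of the
    retained set is order-independent.
    """
    ann = annotation.loc[beta.index]
    if report is None:
        report = QCReport()
    keep = pd.Series(True, index=beta.index)

    def apply(mask: pd.Series, reason: str) -> None:
        nonlocal keep
        newly = keep & ~mask
        report.add_probe_removals(beta.index[newly], reason)
        keep &= mask

    if drop_chrY:
        apply(ann["chrom"] != "chrY", "chrY")
    if drop_contexts:
        apply(~ann["context"].isin(drop_contexts), "context")
    if drop_snp:
        apply(~ann["snp_overlap"].astype(bool), "snp_overlap")
    if drop_cross_reactive:
        apply(~ann["cross_reactive"].astype(bool), "cross_reactive")
    sd = beta.std(axis=1, ddof=1)
    apply(~(sd < sd_min), "low_sd")

    out = beta.loc[keep]
    report.retained_probes = list(out.index)
    report.retained_samples = list(out.columns)
    return out, report


def knn_impute(
    beta: pd.DataFrame,
    k: int = 10,
    max_missing_frac: float = 0.5,
) -> pd.DataFrame:
    """Impute missing entries from the k nearest probes.

    Distance between probes is the Euclidean distance over jointly
    observed samples (no rescaling by the number of shared samples).
    For each missing entry, the imputed value is the mean of the values
    of the ``k`` nearest probes that are observed at that sample; ties
    are broken by probe order. Observed values are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = beta.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    if obs.all():
        return beta.copy()
    miss_frac = 1.0 - obs.mean(axis=1)
    if (miss_frac >= 1.0).any():
        bad = list(beta.index[miss_frac >= 1.0])
        raise ValueError(f"probes with no observed values: {bad[:5]}")
    if (miss_frac > max_missing_frac).any():
        bad = list(beta.index[miss_frac > max_missing_frac])
        raise ValueError(
            f"{len(bad)} probes exceed the missingness cap {max_missing_frac}"
        )
    Xf = np.where(obs, X, 0.0)
    sq = Xf**2
    out = X.copy()
    target_rows = np.flatnonzero(~obs.all(axis=1))
    obs_f = obs.astype(float)
    for i in target_rows:
        # squared distance to every probe over jointly observed samples
        joint = obs_f * obs[i]
        d2 = (sq[i] * joint).sum(axis=1) + (sq * joint).sum(axis=1) - 2.0 * (Xf * (Xf[i] * joint)).sum(axis=1)
        d2[i] = np.inf
        d2[joint.sum(axis=1) == 0] = np.inf
        order = np.argsort(d2, kind="stable")
        for j in np.flatnonzero(~obs[i]):
            donors = order[obs[order, j] & np.isfinite(d2[order])][:k]
            if donors.size == 0:
                raise ValueError(
                    f"no donor probes for entry ({beta.index[i]}, {beta.columns[j]})"
                )
            out[i, j] = X[donors, j].mean()
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


def global_methylation(beta: pd.DataFrame) -> pd.Series:
    """Per-sample mean beta over retained probes (5mC content proxy)."""
    if beta.shape[0] == 0:
        raise ValueError("empty probe set")
    if beta.isna().any().any():
        raise ValueError("matrix must be complete (impute first)")
    return beta.mean(axis=0)


def paired_shift_test(metric_pre, metric_post) -> float:
    """Two-sided Wilcoxon signed-rank p for a paired pre/post shift.

    Zeros are handled by the Pratt method; the null is exact for
    n <= 25 without zero differences, otherwise a normal approximation
    with continuity correction is used. All-zero differences are
    degenerate and return p = 1 with a warning.
    """
    pre = np.asarray(metric_pre, dtype=float)
    post = np.asarray(metric_post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired vectors must have equal length")
    d = post - pre
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; test is degenerate")
        return 1.0
    exact_ok = d.size <= 25 and not np.any(d == 0)
    res = stats.wilcoxon(
        post,
        pre,
        zero_method="pratt",
        correction=not exact_ok,
        method="exact" if exact_ok else "approx",
    )
    return float(res.pvalue)
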