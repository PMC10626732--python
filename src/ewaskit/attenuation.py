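"""Decay of treatment-associated methylation effects over time.

Treated samples are stratified by time between specimen collection and
treatment start (< 0.5 y, 0.5–2 y, > 2 y, unspecified); a single joint
intercept-free model with a five-level treatment factor (reference =
untreated) yields per-feature effects for each stratum-vs-untreated
comparison. Attenuation is summarized by the through-origin
least-squares slope of late-comparison effects on early-comparison
effects — a slope of 1 means no decay, 0 means complete recovery —
and by counts of features that stay significant and shrink
monotonically across comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffmeth import (
    DesignMatrix,
    FeatureFits,
    _expand_covariates,
    _find_collinear,
    ebayes_moderate,
    fit_feature_models,
)

STRATUM_LABELS = ("untreated", "<0.5y", "0.5-2y", ">2y", "unspecified")


def stratify_by_time(
    sheet: pd.DataFrame, cutpoints: tuple[float, float] = (0.5, 2.0)
) -> pd.Series:
    """Per-sample stratum label with half-open bins [0, c1), [c1, c2), [c2, inf).

    Untreated samples pass through as ``untreated``; treated samples
    with missing time become ``unspecified``. Negative times raise.
    """
    c1, c2 = cutpoints
    t = sheet["time_from_treatment_y"].astype(float)
    treated = sheet["treated"].astype(bool)
    if (t.dropna() < 0).any():
        raise ValueError("negative time from treatment start")
    labels = pd.Series("untreated", index=sheet.index, dtype=object)
    labels[treated & t.isna()] = "unspecified"
    labels[treated & (t < c1)] = STRATUM_LABELS[1]
    labels[treated & (t >= c1) & (t < c2)] = STRATUM_LABELS[2]
    labels[treated & (t >= c2)] = STRATUM_LABELS[3]
    labels.name = "stratum"
    return labels


@dataclass
class AttenuationResult:
    """Per-comparison differential results plus slope/persistence summaries."""

    effects: dict[str, pd.DataFrame]  # comparison label -> DiffResult frame
    strata_counts: dict[str, int]


def fit_strata_models(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    strata: pd.Series,
    adjust: list[str] | None = None,
    extra_numeric: pd.DataFrame | None = None,
) -> AttenuationResult:
    """Joint five-level-factor fit; one contrast per stratum vs untreated.

    Empty strata are dropped with a warning. The design shares the
    single-time-point covariate adjustment; all contrasts come from one
    joint fit so residual variances (and their moderation) are shared.
    """
    strata = strata.loc[sheet.index]
    present = [s for s in STRATUM_LABELS if (strata == s).any()]
    if "untreated" not in present:
        raise ValueError("no untreated samples to serve as reference")
    X_cols: dict[str, np.ndarray] = {}
    for s in present:
        X_cols[f"stratum[{s}]"] = (strata == s).to_numpy(dtype=float)
    _expand_covariates(sheet, list(adjust or []), X_cols)
    if extra_numeric is not None:
        for c in extra_numeric.columns:
            X_cols[str(c)] = extra_numeric.loc[sheet.index, c].to_numpy(dtype=float)
    X = pd.DataFrame(X_cols, index=sheet.index)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"collinear design columns: {_find_collinear(X)}")

    results: dict[str, pd.DataFrame] = {}
    for s in present:
        if s == "untreated":
            continue
        if s == "unspecified":
            continue  # no time anchor; not a decay comparison
        contrast = pd.Series(0.0, index=X.columns)
        contrast[f"stratum[{s}]"] = 1.0
        contrast["stratum[untreated]"] = -1.0
        design = DesignMatrix(X=X, contrast=contrast)
        fits = fit_feature_models(beta, design)
        results[f"{s}_vs_untreated"] = ebayes_moderate(fits)
    missing = [s for s in STRATUM_LABELS[1:4] if s not in present]
    if missing:
        warnings.warn(f"empty strata dropped from comparison: {missing}")
    counts = {s: int((strata == s).sum()) for s in present}
    return AttenuationResult(effects=results, strata_counts=counts)


def attenuation_slope(
    effects_early: pd.Series | np.ndarray,
    effects_late: pd.Series | np.ndarray,
    through_origin: bool = True,
) -> tuple[float, float]:
    """Least-squares slope of late effects on early effects.

    Through-origin by default (the comparison is proportional
    attenuation of the same planted effects); ``through_origin=False``
    adds an intercept and returns only the slope and its standard
    error. Raises when the early effects have near-zero variance.
    """
    x = np.asarray(effects_early, dtype=float)
    y = np.asarray(effects_late, dtype=float)
    if x.shape != y.shape:
        raise ValueError("effect vectors must be aligned feature-wise")
    if x.size < 2 or float(np.sum(x**2)) < 1e-12:
        raise ValueError("near-zero variance in early effects")
    if through_origin:
        sxx = float(np.sum(x**2))
        slope = float(np.sum(x * y) / sxx)
        resid = y - slope * x
        dof = max(x.size - 1, 1)
        stderr = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    else:
        X = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        dof = max(x.size - 2, 1)
        s2 = float(np.sum(resid**2) / dof)
        cov = s2 * np.linalg.inv(X.T @ X)
        slope, stderr = float(coef[1]), float(np.sqrt(cov[1, 1]))
    return slope, stderr


def slope_table(
    result: AttenuationResult,
    threshold: float,
    feature_subset: str = "early_significant",
    through_origin: bool = True,
) -> pd.DataFrame:
    """Pairwise attenuation slopes between ordered comparisons.

    By default the slope is computed over features significant in the
    earlier comparison (``feature_subset="all"`` uses every shared
    feature).
    """
    order = [c for c in (f"{s}_vs_untreated" for s in STRATUM_LABELS[1:4])
             if c in result.effects]
    rows = []
    for i, early in enumerate(order):
        for late in order[i + 1 :]:
            e = result.effects[early]
            l = result.effects[late]
            shared = e.index.intersection(l.index)
            if feature_subset == "early_significant":
                shared = shared[e.loc[shared, "p"] < threshold]
            if len(shared) < 2:
                continue
            slope, se = attenuation_slope(
                e.loc[shared, "effect"], l.loc[shared, "effect"],
                through_origin=through_origin,
            )
            rows.append(dict(early=early, late=late, slope=slope,
                             stderr=se, n_features=len(shared)))
    return pd.DataFrame(rows)


def count_persistent(result: AttenuationResult, threshold: float) -> dict:
    """Significance and direction-consistency tallies across comparisons.

    Counts features with p < threshold per comparison; among features
    significant in the latest comparison, flags sign-concordance across
    all comparisons and monotone decrease of |effect| from earliest to
    latest.
    """
    order = [c for c in (f"{s}_vs_untreated" for s in STRATUM_LABELS[1:4])
             if c in result.effects]
    counts = {c: int((result.effects[c]["p"] < threshold).sum()) for c in order}
    summary = {
        "significant_per_comparison": counts,
        "latest_significant": 0,
        "sign_consistent": 0,
        "monotone_decreasing": 0,
    }
    if not order:
        return summary
    latest = order[-1]
    latest_sig = result.effects[latest].index[result.effects[latest]["p"] < threshold]
    shared = latest_sig
    for c in order:
        shared = shared.intersection(result.effects[c].index)
    summary["latest_significant"] = len(shared)
    for f in shared:
        effs = np.array([result.effects[c].at[f, "effect"] for c in order])
        if np.all(effs > 0) or np.all(effs < 0):
            summary["sign_consistent"] += 1
            mags = np.abs(effs)
            if np.all(np.diff(mags) < 0):
                summary["monotone_decreasing"] += 1
    return summary
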