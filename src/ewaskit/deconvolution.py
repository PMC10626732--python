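"""Reference-based cell-type deconvolution and immune-content scoring.

Cell fractions are inferred per sample by robust partial correlations
(RPC): a Huber-loss robust regression of the sample's marker-probe
betas on the reference cell-type profiles, with negative coefficients
truncated at zero and the remainder renormalized to sum to one (the
renormalization keeps the fractions well-scaled for use as model
covariates). Immune content is scored LUMP-style from probes that are
unmethylated in leukocytes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .qc import QCReport

#: scaling constant of the leukocyte-unmethylation purity estimator
LUMP_SCALE = 0.85


@dataclass
class CellFractions:
    fractions: pd.DataFrame  # samples x cell types
    method: str = "RPC"


@dataclass
class ImmuneContent:
    scores: pd.Series  # per-sample, in [0, 1]
    probes_used: list[str]


def rpc_fractions(
    beta: pd.DataFrame,
    reference: pd.DataFrame,
    min_marker_frac: float = 0.8,
    huber_t: float = 1.345,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CellFractions:
    """Robust-partial-correlation cell fractions per sample.

    Requires at least ``min_marker_frac`` of the reference marker probes
    to be present in the (QC'd) beta matrix; the regression includes an
    intercept, which is discarded before truncation and renormalization.
    """
    shared = reference.index.intersection(beta.index)
    if len(shared) < min_marker_frac * len(reference.index):
        raise ValueError(
            f"only {len(shared)}/{len(reference.index)} reference marker probes "
            "present after QC (excessive marker dropout)"
        )
    R = reference.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < R.shape[1]:
        raise ValueError("rank-deficient reference methylome")
    X = sm.add_constant(R, prepend=True)
    Y = beta.loc[shared].to_numpy(dtype=float)
    norm = sm.robust.norms.HuberT(t=huber_t)
    out = np.empty((beta.shape[1], reference.shape[1]))
    for j in range(beta.shape[1]):
        fit = sm.RLM(Y[:, j], X, M=norm).fit(maxiter=max_iter, tol=tol)
        coefs = np.maximum(fit.params[1:], 0.0)
        total = coefs.sum()
        out[j] = coefs / total if total > 0 else np.full(len(coefs), 1.0 / len(coefs))
    fr = pd.DataFrame(out, index=beta.columns, columns=reference.columns)
    return CellFractions(fractions=fr, method="RPC")


def lump_score(beta: pd.DataFrame, lump_probes) -> ImmuneContent:
    """Leukocyte-unmethylation purity score per sample.

    score = min(1, mean(1 - beta over purity probes) / 0.85).
    """
    probes = pd.Index(lump_probes).intersection(beta.index)
    if len(probes) == 0:
        raise ValueError("no purity probes present in the beta matrix")
    unmeth = (1.0 - beta.loc[probes]).mean(axis=0)
    scores = np.minimum(1.0, unmeth / LUMP_SCALE)
    return ImmuneContent(scores=scores, probes_used=list(probes))


def purity_filter(
    scores: ImmuneContent | pd.Series,
    min_score: float = 0.9,
    report: QCReport | None = None,
) -> list[str]:
    """Retain samples with immune-content score >= ``min_score``."""
    s = scores.scores if isinstance(scores, ImmuneContent) else scores
    retained = list(s.index[s >= min_score])
    if report is not None:
        report.add_sample_removals(s.index[s < min_score], "low_purity")
        report.retained_samples = retained
    return retained
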