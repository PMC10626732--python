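"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ewaskit.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def paired_cohort():
    """Small paired pre/post cohort with planted effects."""
    cfg = SimulationConfig(
        n_probes=2_000, n_promoters=200, n_markers_per_type=20,
        design="paired", n_pairs=40, n_lump_probes=40,
        frac_causal_probes=0.02, frac_causal_promoters=0.05, seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def single_cohort():
    """Small single-time-point cohort (treated/untreated, blood)."""
    cfg = SimulationConfig(
        n_probes=2_000, n_promoters=200, n_markers_per_type=20,
        design="single", n_treated=120, n_untreated=80, n_lump_probes=40,
        frac_causal_probes=0.02, frac_causal_promoters=0.05,
        batch_count=3, seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_single_cohort():
    """Single-time-point cohort with no treatment effect (delta = 0)."""
    cfg = SimulationConfig(
        n_probes=1_200, n_promoters=250, n_markers_per_type=15,
        design="single", n_treated=60, n_untreated=60, n_lump_probes=30,
        effect_size_delta=0.0, frac_missing=0.0, frac_elevated_detp=0.0,
        batch_count=2, seed=19,
    )
    return simulate_cohort(cfg)


def make_paired_sheet(n_subj: int, rng=None) -> pd.DataFrame:
    """Minimal paired sample sheet (pre/post per subject)."""
    rows = []
    for s in range(n_subj):
        for tp in ("pre", "post"):
            rows.append(
                dict(sample_id=f"S{s}_{tp}", subject_id=f"S{s}", timepoint=tp,
                     treated=tp == "post")
            )
    return pd.DataFrame(rows).set_index("sample_id")
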