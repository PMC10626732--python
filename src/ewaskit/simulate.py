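"""Synthetic methylation cohorts with planted ground truth.

The generator emulates the statistical structure of a blood/saliva
methylation-array study of treatment effects:

* per-sample methylomes are convex mixtures of cell-type reference
  profiles (7 blood leukocyte subtypes, or leukocyte/epithelial for
  saliva) at marker probes, with a shared bimodal background elsewhere;
* treated samples carry signed beta-scale shifts at planted causal
  probes/promoters that decay exponentially with time since treatment
  start (half-life in years);
* per-(probe, batch) offsets, per-subject random effects, type-II
  probe compression (so design normalization has structure to correct),
  beta-distributed observation noise, and sporadic detection failures /
  missing entries.

Every draw flows from the config seed; a fixed config reproduces the
bundle bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

BLOOD_CELL_TYPES = ("Bcell", "NK", "CD4T", "CD8T", "Mono", "Neutro", "Eosino")
SALIVA_CELL_TYPES = ("Leuko", "Epi")

# three-state background (unmethylated / hemi-methylated / methylated);
# weights set so the genome-wide mean beta sits near 0.655, the level
# typical of whole-blood leukocyte methylomes
_BACKGROUND_MEANS = (0.08, 0.50, 0.92)
_BACKGROUND_WEIGHTS = (0.25, 0.13, 0.62)

#: latent beta at leukocyte-unmethylated purity probes; gives LUMP scores
#: of (1 - 0.16)/0.85 ~ 0.988 for pure blood
_LUMP_PROBE_LEVEL = 0.16

_CONTEXTS_OTHER = ("CC", "CAG", "CAH", "CTG", "CTH", "Other")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Cohort sizes default to the designs the pipeline targets: 125
    pre/post pairs in the paired arm; 1,066 treated / 742 untreated
    blood samples (207 / 130 for saliva) in the single-time-point arm.
    Probe/promoter counts default to a desk-scale methylome.
    """

    n_probes: int = 20_000
    n_promoters: int = 1_000
    probes_per_promoter: tuple[int, int] = (2, 8)
    n_celltypes: int = 7
    n_markers_per_type: int = 47
    design: str = "paired"  # "paired" or "single"
    n_pairs: int = 125
    n_treated: int = 1_066
    n_untreated: int = 742
    specimen: str = "blood"  # "blood" or "saliva"
    frac_causal_probes: float = 0.01
    frac_causal_promoters: float = 0.02
    effect_size_delta: float = 0.1
    decay_halflife: float = 1.0  # years; inf = no decay
    batch_count: int = 5
    noise_precision: float = 100.0
    dirichlet_alpha: Sequence[float] | None = None
    # times (years since treatment start) at sample draw
    paired_post_time_range: tuple[float, float] = (0.02, 0.3)
    time_strata_props: tuple[float, float, float, float] = (0.20, 0.45, 0.30, 0.05)
    batch_sd: float = 0.005
    subject_sd: float = 0.01
    type2_frac: float = 0.70
    type2_shrink: float = 1.6  # logit-scale compression divisor for type-II probes
    frac_elevated_detp: float = 0.002
    frac_missing: float = 0.001
    n_bad_samples: int = 0  # samples with wholesale detection failure
    n_low_purity_samples: int = 0  # samples diluted with non-immune DNA
    n_lump_probes: int = 100
    seed: int = 0
    #: when set, the probe annotation and planted causal features are drawn
    #: from this seed instead of ``seed``, so independently noised cohorts
    #: share the same feature universe and truth (replication designs)
    causal_seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_probes", "n_promoters", "n_celltypes", "batch_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.design not in ("paired", "single"):
            raise ValueError("design must be 'paired' or 'single'")
        if self.specimen not in ("blood", "saliva"):
            raise ValueError("specimen must be 'blood' or 'saliva'")
        for name in ("frac_causal_probes", "frac_causal_promoters"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dirichlet_alpha is not None:
            alpha = np.asarray(self.dirichlet_alpha, dtype=float)
            if alpha.shape != (self.n_celltypes,) or np.any(alpha <= 0):
                raise ValueError("dirichlet_alpha must be strictly positive, one per cell type")
        n_causal = int(round(self.frac_causal_probes * self.n_probes))
        if n_causal > self.n_probes:
            raise ValueError("causal probe count exceeds probe count")

    def cell_types(self) -> tuple[str, ...]:
        base = SALIVA_CELL_TYPES if self.specimen == "saliva" else BLOOD_CELL_TYPES
        if self.n_celltypes <= len(base):
            return base[: self.n_celltypes]
        return base + tuple(f"Cell{i}" for i in range(len(base), self.n_celltypes))

    def default_dirichlet_alpha(self) -> np.ndarray:
        if self.dirichlet_alpha is not None:
            return np.asarray(self.dirichlet_alpha, dtype=float)
        if self.specimen == "saliva" and self.n_celltypes == 2:
            props = np.array([0.8, 0.2])
        else:
            # leukocyte proportions: granulocytes dominate, lymphocytes minor
            base = np.array([0.02, 0.02, 0.04, 0.09, 0.06, 0.72, 0.05])
            props = base[: self.n_celltypes]
            props = props / props.sum()
        return 60.0 * props


@dataclass
class TruthRecord:
    """Ground truth planted by :func:`simulate_cohort`."""

    causal_probe_ids: set[str]
    causal_promoter_ids: set[str]
    true_delta_per_probe: dict[str, float]
    true_fractions: pd.DataFrame  # samples x cell types
    true_decay_halflife: float
    enriched_set_ids: set[str] = field(default_factory=set)
    latent_means: pd.DataFrame | None = None  # probes x samples, pre-noise
    low_purity_samples: set[str] = field(default_factory=set)
    bad_samples: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        d = {
            "causal_probe_ids": sorted(self.causal_probe_ids),
            "causal_promoter_ids": sorted(self.causal_promoter_ids),
            "true_delta_per_probe": self.true_delta_per_probe,
            "true_decay_halflife": self.true_decay_halflife,
            "enriched_set_ids": sorted(self.enriched_set_ids),
            "low_purity_samples": sorted(self.low_purity_samples),
            "bad_samples": sorted(self.bad_samples),
            "true_fractions": self.true_fractions.to_dict(orient="index"),
        }
        return d


@dataclass
class SimulatedCohort:
    """Bundle returned by :func:`simulate_cohort`."""

    beta: pd.DataFrame  # probes x samples, may contain NaN
    detection_p: pd.DataFrame
    sheet: pd.DataFrame  # samples x covariates
    annotation: pd.DataFrame  # indexed by probe_id
    reference: pd.DataFrame  # marker probes x cell types
    lump_probes: list[str]
    truth: TruthRecord
    config: SimulationConfig


def make_reference_profiles(
    n_probes: int,
    n_celltypes: int,
    n_markers_per_type: int,
    seed: int,
    cell_types: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Reference methylome with type-specific marker blocks.

    Each cell type owns ``n_markers_per_type`` marker probes at which its
    beta differs from every other type's by at least 0.5: alternating
    hypo-methylated (own type low, others high) and hyper-methylated
    blocks, mimicking tsDHS-DMC style references. Remaining probes carry
    a shared background level.
    """
    if n_probes <= 0 or n_celltypes <= 0 or n_markers_per_type <= 0:
        raise ValueError("dimensions must be positive")
    if n_markers_per_type * n_celltypes > n_probes:
        raise ValueError("marker probes exceed probe count")
    rng = np.random.default_rng(seed)
    if cell_types is None:
        cell_types = [f"Cell{k}" for k in range(n_celltypes)]
    ref = np.empty((n_probes, n_celltypes))
    background = _draw_background_means(rng, n_probes)
    ref[:] = background[:, None]
    for k in range(n_celltypes):
        rows = slice(k * n_markers_per_type, (k + 1) * n_markers_per_type)
        n = n_markers_per_type
        own = np.where(np.arange(n) % 2 == 0, 0.06, 0.92)
        other = np.where(np.arange(n) % 2 == 0, 0.88, 0.22)
        jitter_own = rng.uniform(-0.02, 0.02, size=n)
        jitter_other = rng.uniform(-0.02, 0.02, size=(n, n_celltypes))
        block = other[:, None] + jitter_other
        block[:, k] = own + jitter_own
        ref[rows] = np.clip(block, 0.01, 0.99)
    probe_ids = [f"cg{i:07d}" for i in range(n_probes)]
    return pd.DataFrame(ref, index=probe_ids, columns=list(cell_types))


def _draw_background_means(rng: np.random.Generator, n: int) -> np.ndarray:
    """Trimodal background probe means (unmethylated / hemi / methylated)."""
    state = rng.choice(3, size=n, p=_BACKGROUND_WEIGHTS)
    mu = np.asarray(_BACKGROUND_MEANS)[state] + rng.normal(0.0, 0.04, size=n)
    return np.clip(mu, 0.02, 0.98)


def _logit(x: np.ndarray) -> np.ndarray:
    return np.log(x) - np.log1p(-x)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate one cohort (paired or single-time-point arm) with truth.

    Latent mean per sample = mixture of reference profiles at marker
    probes, background elsewhere; treated samples get the planted delta
    at causal probes scaled by ``exp(-ln2 * t / halflife)``; batch and
    subject offsets are added on the beta scale; type-II probes are
    compressed toward 0.5 on the logit scale; observed beta ~
    Beta(mu*nu, (1-mu)*nu) with nu = ``noise_precision``.
    """
    rng = np.random.default_rng(config.seed)
    feat_rng = (
        rng if config.causal_seed is None
        else np.random.default_rng(config.causal_seed)
    )
    cell_types = config.cell_types()
    n_probes = config.n_probes

    # ---- probe universe and annotation -------------------------------
    probe_ids = np.array([f"cg{i:07d}" for i in range(n_probes)])
    annotation = _build_annotation(feat_rng, config, probe_ids)

    # ---- reference profiles at marker probes -------------------------
    n_marker = config.n_markers_per_type * config.n_celltypes
    marker_ref = make_reference_profiles(
        n_marker, config.n_celltypes, config.n_markers_per_type,
        seed=int(feat_rng.integers(2**31)), cell_types=cell_types,
    )
    # embed markers into the probe universe: markers occupy the first
    # clean (CG-context, unflagged, autosome/X) probe slots
    clean = (
        (annotation["context"] == "CG")
        & ~annotation["snp_overlap"]
        & ~annotation["cross_reactive"]
        & (annotation["chrom"] != "chrY")
    )
    clean_idx = np.flatnonzero(clean.to_numpy())
    if clean_idx.size < n_marker + config.n_lump_probes:
        raise ValueError("probe universe too small for markers and purity probes")
    marker_idx = clean_idx[:n_marker]
    lump_idx = clean_idx[n_marker : n_marker + config.n_lump_probes]
    marker_ref.index = probe_ids[marker_idx]
    # markers and purity probes are type I (references are built from
    # well-behaved probes), so the reference matches emitted betas
    annotation.iloc[marker_idx, annotation.columns.get_loc("design_class")] = "I"
    annotation.iloc[lump_idx, annotation.columns.get_loc("design_class")] = "I"

    # ---- per-probe latent reference matrix (probes x cell types) -----
    background = _draw_background_means(feat_rng, n_probes)
    ref_full = np.repeat(background[:, None], config.n_celltypes, axis=1)
    ref_full[marker_idx] = marker_ref.to_numpy()
    if config.specimen == "saliva" and config.n_celltypes == 2:
        # purity probes separate leukocytes from epithelium
        ref_full[lump_idx, 0] = _LUMP_PROBE_LEVEL
        ref_full[lump_idx, 1] = 0.85
    else:
        ref_full[lump_idx] = _LUMP_PROBE_LEVEL

    # ---- causal features ---------------------------------------------
    truth_delta, causal_probes, causal_promoters = _plant_effects(
        feat_rng, config, annotation, marker_idx, lump_idx
    )

    # ---- samples ------------------------------------------------------
    sheet = _build_sample_sheet(rng, config)
    n_samples = len(sheet)
    alpha = config.default_dirichlet_alpha()
    fractions = rng.dirichlet(alpha, size=n_samples)
    if config.design == "paired":
        # post-treatment monocyte expansion (paired arm); redraw post rows
        # with inflated monocyte concentration while sharing the subject seed
        mono = list(cell_types).index("Mono") if "Mono" in cell_types else None
        if mono is not None:
            post = (sheet["timepoint"] == "post").to_numpy()
            alpha_post = alpha.copy()
            alpha_post[mono] *= 1.3
            fractions[post] = rng.dirichlet(alpha_post, size=int(post.sum()))
    if config.n_low_purity_samples:
        # dilute the last samples with non-immune (methylated-at-purity-probe) DNA
        low = rng.choice(n_samples, size=config.n_low_purity_samples, replace=False)
    else:
        low = np.array([], dtype=int)
    frac_df = pd.DataFrame(fractions, index=sheet.index, columns=list(cell_types))

    # latent mean matrix (probes x samples)
    latent = ref_full @ fractions.T
    if low.size:
        # mix 40% foreign epithelial-like DNA: purity probes become methylated
        foreign = background.copy()
        foreign[lump_idx] = 0.85
        latent[:, low] = 0.6 * latent[:, low] + 0.4 * foreign[:, None]

    # treatment effect with exponential decay
    years = sheet["time_from_treatment_y"].to_numpy(dtype=float)
    treated = sheet["treated"].to_numpy(dtype=bool)
    if np.isfinite(config.decay_halflife):
        decay = np.exp(-np.log(2.0) * np.nan_to_num(years, nan=0.0) / config.decay_halflife)
    else:
        decay = np.ones(n_samples)
    effect = np.where(treated, decay, 0.0)
    delta_col = np.zeros(n_probes)
    causal_pos = annotation.index.get_indexer(list(truth_delta.keys()))
    delta_col[causal_pos] = np.fromiter(truth_delta.values(), dtype=float)
    latent = latent + delta_col[:, None] * effect[None, :]

    # subject random effect (paired arm shares it across the pair)
    if config.subject_sd > 0:
        subj_codes, subj_idx = np.unique(sheet["subject_id"], return_inverse=True)
        subj_eff = rng.normal(0.0, config.subject_sd, size=len(subj_codes))
        latent = latent + subj_eff[subj_idx][None, :]

    # per-(probe, batch) offsets
    if config.batch_sd > 0 and config.batch_count > 1:
        batch_codes, batch_idx = np.unique(sheet["batch"], return_inverse=True)
        batch_eff = rng.normal(0.0, config.batch_sd, size=(n_probes, len(batch_codes)))
        latent = latent + batch_eff[:, batch_idx]

    latent = np.clip(latent, 1e-4, 1 - 1e-4)
    latent_df = pd.DataFrame(latent, index=probe_ids, columns=sheet.index)

    # type-II compression on the logit scale
    observed_mean = latent.copy()
    is_t2 = (annotation["design_class"] == "II").to_numpy()
    observed_mean[is_t2] = _expit(_logit(observed_mean[is_t2]) / config.type2_shrink)

    # beta observation noise
    nu = config.noise_precision
    if np.isfinite(nu):
        a = observed_mean * nu
        b = (1.0 - observed_mean) * nu
        beta = rng.beta(a, b)
    else:
        beta = observed_mean.copy()

    # detection p-values: background small, sporadic elevated entries,
    # planted bad samples fail wholesale
    detp = rng.uniform(0.0, 0.005, size=beta.shape)
    elevated = rng.random(beta.shape) < config.frac_elevated_detp
    detp[elevated] = rng.uniform(0.02, 0.6, size=int(elevated.sum()))
    bad = np.array([], dtype=int)
    if config.n_bad_samples:
        candidates = np.setdiff1d(np.arange(n_samples), low)
        bad = rng.choice(candidates, size=config.n_bad_samples, replace=False)
        detp[:, bad] = rng.uniform(0.02, 0.9, size=(n_probes, bad.size))
    missing = rng.random(beta.shape) < config.frac_missing
    beta[missing] = np.nan

    beta_df = pd.DataFrame(beta, index=probe_ids, columns=sheet.index)
    detp_df = pd.DataFrame(detp, index=probe_ids, columns=sheet.index)

    truth = TruthRecord(
        causal_probe_ids=set(truth_delta),
        causal_promoter_ids=causal_promoters,
        true_delta_per_probe=truth_delta,
        true_fractions=frac_df,
        true_decay_halflife=config.decay_halflife,
        latent_means=latent_df,
        low_purity_samples=set(sheet.index[low]),
        bad_samples=set(sheet.index[bad]),
    )
    return SimulatedCohort(
        beta=beta_df,
        detection_p=detp_df,
        sheet=sheet,
        annotation=annotation,
        reference=marker_ref,
        lump_probes=list(probe_ids[lump_idx]),
        truth=truth,
        config=config,
    )


def _build_annotation(
    rng: np.random.Generator, config: SimulationConfig, probe_ids: np.ndarray
) -> pd.DataFrame:
    n = config.n_probes
    lo, hi = config.probes_per_promoter
    sizes = rng.integers(lo, hi + 1, size=config.n_promoters)
    promoter_id = np.full(n, "", dtype=object)
    gene_id = np.full(n, "", dtype=object)
    pos = 0
    for j, size in enumerate(sizes):
        if pos + size > n:
            break
        promoter_id[pos : pos + size] = f"PRM{j:05d}"
        gene_id[pos : pos + size] = f"GENE{j:05d}"
        pos += size
    chroms = [f"chr{i}" for i in range(1, 23)] + ["chrX"]
    chrom = rng.choice(chroms, size=n)
    chrom[rng.random(n) < 0.005] = "chrY"
    start = rng.integers(10_000, 200_000_000, size=n)
    design = np.where(rng.random(n) < config.type2_frac, "II", "I")
    context = np.full(n, "CG", dtype=object)
    other = rng.random(n) < 0.03
    context[other] = rng.choice(_CONTEXTS_OTHER, size=int(other.sum()))
    ann = pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": start + 2,
            "design_class": design,
            "context": context,
            "snp_overlap": rng.random(n) < 0.01,
            "cross_reactive": rng.random(n) < 0.01,
            "promoter_id": promoter_id,
            "gene_id": gene_id,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ann


def _plant_effects(
    rng: np.random.Generator,
    config: SimulationConfig,
    annotation: pd.DataFrame,
    marker_idx: np.ndarray,
    lump_idx: np.ndarray,
) -> tuple[dict[str, float], set[str], set[str]]:
    """Choose causal promoters (coherent sign per promoter) and extra
    isolated causal probes among clean, filter-surviving probes."""
    reserved = set(marker_idx) | set(lump_idx)
    eligible = (
        (annotation["context"] == "CG")
        & ~annotation["snp_overlap"]
        & ~annotation["cross_reactive"]
        & (annotation["chrom"] != "chrY")
    )
    eligible_idx = np.array(
        [i for i in np.flatnonzero(eligible.to_numpy()) if i not in reserved]
    )
    promoters = annotation["promoter_id"].to_numpy()
    delta: dict[str, float] = {}
    causal_promoters: set[str] = set()

    n_causal_prom = int(round(config.frac_causal_promoters * config.n_promoters))
    prom_of_eligible = promoters[eligible_idx]
    unique_proms = [p for p in pd.unique(prom_of_eligible) if p]
    rng.shuffle(unique_proms)
    chosen = unique_proms[:n_causal_prom]
    for j, prom in enumerate(chosen):
        sign = 1.0 if j % 2 == 0 else -1.0
        causal_promoters.add(prom)
        rows = eligible_idx[prom_of_eligible == prom]
        for i in rows:
            delta[annotation.index[i]] = sign * config.effect_size_delta

    n_causal_target = int(round(config.frac_causal_probes * config.n_probes))
    remaining = [i for i in eligible_idx if annotation.index[i] not in delta]
    rng.shuffle(remaining)
    for i in remaining:
        if len(delta) >= n_causal_target:
            break
        sign = 1.0 if rng.random() < 0.5 else -1.0
        delta[annotation.index[i]] = sign * config.effect_size_delta
    return delta, set(delta), causal_promoters


def _build_sample_sheet(rng: np.random.Generator, config: SimulationConfig) -> pd.DataFrame:
    rows = []
    if config.design == "paired":
        t_lo, t_hi = config.paired_post_time_range
        for s in range(config.n_pairs):
            subj = f"SUBJ{s:04d}"
            batch = f"B{int(rng.integers(config.batch_count)) + 1}"
            age = float(np.clip(rng.normal(56, 10), 25, 85))
            eth = "Chinese" if rng.random() < 0.79 else "Other"
            year = int(rng.integers(2012, 2022))
            t_post = float(rng.uniform(t_lo, t_hi))
            common = dict(
                subject_id=subj, specimen=config.specimen, batch=batch,
                age=age, ethnicity=eth, diagnosis_year=year,
            )
            rows.append(dict(sample_id=f"{subj}_pre", timepoint="pre", treated=False,
                             time_from_treatment_y=np.nan, **common))
            rows.append(dict(sample_id=f"{subj}_post", timepoint="post", treated=True,
                             time_from_treatment_y=t_post, **common))
    else:
        props = np.asarray(config.time_strata_props, dtype=float)
        props = props / props.sum()
        strata = rng.choice(4, size=config.n_treated, p=props)
        k = 0
        for s in range(config.n_treated + config.n_untreated):
            subj = f"SUBJ{s:04d}"
            treated = s < config.n_treated
            if treated:
                stratum = strata[k]
                k += 1
                if stratum == 0:
                    t = float(rng.uniform(0.05, 0.5))
                elif stratum == 1:
                    t = float(rng.uniform(0.5, 2.0))
                elif stratum == 2:
                    t = float(rng.uniform(2.0, 6.0))
                else:
                    t = np.nan  # unspecified: date unknown
            else:
                t = np.nan
            rows.append(dict(
                sample_id=subj, subject_id=subj, timepoint="single",
                treated=treated, time_from_treatment_y=t,
                specimen=config.specimen,
                batch=f"B{int(rng.integers(config.batch_count)) + 1}",
                age=float(np.clip(rng.normal(56, 10), 25, 85)),
                ethnicity="Chinese" if rng.random() < 0.79 else "Other",
                diagnosis_year=int(rng.integers(2009, 2019)),
            ))
    sheet = pd.DataFrame(rows).set_index("sample_id")
    return sheet


def make_gene_sets(
    truth: TruthRecord,
    annotation: pd.DataFrame,
    n_sets: int = 100,
    set_size_range: tuple[int, int] = (10, 50),
    n_enriched: int = 5,
    seed: int = 0,
    causal_member_frac: float = 0.7,
) -> dict[str, list[str]]:
    """GMT-style gene-set collection over the promoter gene universe.

    Enriched sets over-represent genes of causal promoters of one
    effect sign each (alternating suppressed / activated), so planted
    sets concentrate at one extreme of a signed ranking. Enriched set
    IDs are recorded in ``truth.enriched_set_ids``.
    """
    if n_enriched > n_sets:
        raise ValueError("n_enriched cannot exceed n_sets")
    lo, hi = set_size_range
    if lo < 10 or hi > 500 or lo > hi:
        raise ValueError("set sizes must lie within [10, 500]")
    rng = np.random.default_rng(seed)
    prom2gene = (
        annotation.loc[annotation["promoter_id"] != "", ["promoter_id", "gene_id"]]
        .drop_duplicates("promoter_id")
        .set_index("promoter_id")["gene_id"]
    )
    universe = sorted(prom2gene.unique())
    causal_sign: dict[str, float] = {}
    for pid, d in truth.true_delta_per_probe.items():
        prom = annotation.at[pid, "promoter_id"]
        if prom and prom in truth.causal_promoter_ids:
            causal_sign[prom2gene[prom]] = np.sign(d)
    pos_genes = sorted(g for g, s in causal_sign.items() if s > 0)
    neg_genes = sorted(g for g, s in causal_sign.items() if s < 0)

    sets: dict[str, list[str]] = {}
    truth.enriched_set_ids = set()
    for j in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        name = f"SET{j:04d}"
        if j < n_enriched:
            pool = neg_genes if j % 2 == 0 else pos_genes
            n_causal = min(len(pool), max(1, int(round(causal_member_frac * size))))
            members = list(rng.choice(pool, size=n_causal, replace=False))
            rest = [g for g in universe if g not in members]
            members += list(rng.choice(rest, size=size - n_causal, replace=False))
            direction = "suppressed" if j % 2 == 0 else "activated"
            name = f"SET{j:04d}_{direction}"
            truth.enriched_set_ids.add(name)
        else:
            members = list(rng.choice(universe, size=size, replace=False))
        sets[name] = sorted(members)
    return sets
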