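"""End-to-end orchestration: simulate -> QC -> deconvolve -> differential
methylation -> enrichment -> attenuation, with a provenance manifest.

Every stage writes plain-text tables into the configured output
directory; the manifest records the config hash, seeds, per-stage
counts and SHA-256 digests of every output file, so a rerun under the
same config can be verified byte for byte.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import attenuation as att
from . import bmiq, deconvolution, diffmeth, enrichment, io, qc
from .config import PipelineConfig
from .simulate import SimulatedCohort, make_gene_sets, simulate_cohort


def run_pipeline(config: PipelineConfig, cohort: SimulatedCohort | None = None) -> dict:
    """Execute the configured stages; returns the provenance manifest.

    When ``cohort`` is None the synthetic-data stage generates one from
    ``config.simulation`` (seeded by ``config.seed`` unless the
    simulation block pins its own seed).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_sha256": config.digest(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    # ---- simulate -----------------------------------------------------
    if cohort is None:
        sim_cfg = config.simulation
        if sim_cfg.seed == 0 and config.seed != 0:
            sim_cfg = dataclasses_replace(sim_cfg, seed=config.seed)
        cohort = simulate_cohort(sim_cfg)
    io.write_matrix(cohort.beta, outdir / "beta_raw.tsv")
    io.write_matrix(cohort.detection_p, outdir / "detection_p.tsv")
    io.write_sample_sheet(cohort.sheet, outdir / "sample_sheet.csv")
    io.write_annotation(cohort.annotation, outdir / "probe_annotation.bed.tsv")
    io.write_json(cohort.truth.to_dict(), outdir / "truth.json")
    manifest["stages"]["simulate"] = {
        "n_probes": int(cohort.beta.shape[0]),
        "n_samples": int(cohort.beta.shape[1]),
        "design": cohort.config.design,
    }

    # ---- QC -----------------------------------------------------------
    probes, samples, report = qc.greedycut_filter(
        cohort.detection_p, alpha=config.detection_alpha,
        stop_frac=config.greedycut_stop_frac,
    )
    beta = cohort.beta.loc[probes, samples]
    beta = qc.mask_failed_entries(beta, cohort.detection_p, config.detection_alpha)
    if config.run_bmiq:
        beta = bmiq.bmiq_matrix(beta, cohort.annotation)
    beta, report = qc.filter_probes(
        beta, cohort.annotation, sd_min=config.sd_min, report=report
    )
    beta = qc.knn_impute(beta, k=config.knn_k)
    global_meth = qc.global_methylation(beta)
    global_meth.rename("global_methylation").to_frame().to_csv(
        outdir / "global_methylation.tsv", sep="\t", float_format=io.FLOAT_FORMAT
    )
    manifest["stages"]["qc"] = report.counts()

    # ---- deconvolution ------------------------------------------------
    fractions = deconvolution.rpc_fractions(beta, cohort.reference)
    lump = deconvolution.lump_score(beta, cohort.lump_probes)
    retained = deconvolution.purity_filter(lump, config.purity_min, report=report)
    beta = beta[retained]
    sheet = cohort.sheet.loc[retained]
    if cohort.config.design == "paired":
        # both members of a pair must survive
        full = sheet.groupby("subject_id")["timepoint"].transform("nunique") == 2
        sheet = sheet[full]
        beta = beta[sheet.index]
    frac_df = fractions.fractions.loc[sheet.index]
    frac_df.to_csv(outdir / "cell_fractions.tsv", sep="\t",
                   float_format=io.FLOAT_FORMAT, index_label="sample_id")
    lump.scores.loc[sheet.index].rename("lump").to_frame().to_csv(
        outdir / "lump_scores.tsv", sep="\t", float_format=io.FLOAT_FORMAT
    )
    manifest["stages"]["deconvolution"] = {
        "n_samples_retained": int(len(sheet)),
        "n_low_purity_removed": int(
            sum(1 for r in report.removed_samples.values() if r == "low_purity")
        ),
    }

    # ---- differential methylation ------------------------------------
    mode = cohort.config.design
    if mode == "paired":
        mono = frac_df[["Mono"]] if "Mono" in frac_df else None
        design = diffmeth.build_design(sheet, "paired", extra_numeric=mono)
        adjust: list[str] = []
    else:
        adjust = ["batch", "age", "ethnicity", "diagnosis_year"]
        extra = pd.concat(
            [lump.scores.loc[sheet.index].rename("lump"),
             frac_df.iloc[:, :-1]], axis=1
        )
        design = diffmeth.build_design(sheet, "single", adjust=adjust, extra_numeric=extra)
    fits = diffmeth.fit_feature_models(beta, design)
    probe_thr = diffmeth.bonferroni_threshold(len(beta), config.alpha)
    probe_res = diffmeth.call_significant(diffmeth.ebayes_moderate(fits), probe_thr)
    probe_res.to_csv(outdir / "diff_probes.tsv", sep="\t", float_format=io.FLOAT_FORMAT)

    regions = diffmeth.build_region_map(cohort.annotation)
    prom_beta = diffmeth.aggregate_promoters(beta, regions)
    prom_fits = diffmeth.fit_feature_models(prom_beta, design)
    prom_thr = diffmeth.bonferroni_threshold(len(prom_beta), config.alpha)
    prom_res = diffmeth.call_significant(diffmeth.ebayes_moderate(prom_fits), prom_thr)
    prom_res.to_csv(outdir / "diff_promoters.tsv", sep="\t", float_format=io.FLOAT_FORMAT)
    manifest["stages"]["diffmeth"] = {
        "probe_threshold": probe_thr,
        "promoter_threshold": prom_thr,
        "n_significant_probes": int(probe_res["significant"].sum()),
        "n_significant_promoters": int(prom_res["significant"].sum()),
    }

    # ---- enrichment ---------------------------------------------------
    if config.run_gsea:
        gene_sets = make_gene_sets(
            cohort.truth, cohort.annotation, n_sets=config.n_gene_sets,
            set_size_range=config.gene_set_size_range,
            n_enriched=config.n_enriched_sets, seed=cohort.config.seed,
        )
        io.write_gmt(gene_sets, outdir / "gene_sets.gmt")
        gene_map = regions.drop_duplicates("promoter_id").set_index("promoter_id")["gene_id"]
        gcfg = enrichment.GseaConfig(
            exponent=config.gsea_exponent, min_size=config.gsea_min_size,
            max_size=config.gsea_max_size, n_perm_genes=config.n_perm_genes,
            n_perm_labels=config.n_perm_labels, seed=config.seed,
        )
        label_p = None
        if config.run_label_permutation and mode == "single":
            label_p = enrichment.label_permutation_null(
                prom_beta, sheet, regions, gene_sets,
                n_perm=config.n_perm_labels, seed=config.seed,
                adjust=adjust,
                extra_numeric=pd.concat(
                    [lump.scores.loc[sheet.index].rename("lump"),
                     frac_df.iloc[:, :-1]], axis=1,
                ),
                exponent=config.gsea_exponent,
                min_size=config.gsea_min_size, max_size=config.gsea_max_size,
            )
        gsea_table = enrichment.run_gsea(prom_res, gene_sets, gene_map, gcfg, label_p)
        gsea_table.to_csv(outdir / "gsea.tsv", sep="\t", float_format=io.FLOAT_FORMAT)
        io.write_json(enrichment.top_sets_summary(gsea_table), outdir / "gsea_summary.json")
        manifest["stages"]["gsea"] = {"n_sets_tested": int(len(gsea_table))}

    # ---- attenuation --------------------------------------------------
    if config.run_attenuation and mode == "single":
        strata = att.stratify_by_time(sheet)
        extra = pd.concat(
            [lump.scores.loc[sheet.index].rename("lump"), frac_df.iloc[:, :-1]], axis=1
        )
        strata_res = att.fit_strata_models(
            beta, sheet, strata, adjust=adjust, extra_numeric=extra
        )
        slopes = att.slope_table(strata_res, probe_thr)
        slopes.to_csv(outdir / "attenuation_slopes.tsv", sep="\t",
                      float_format=io.FLOAT_FORMAT, index=False)
        persist = att.count_persistent(strata_res, probe_thr)
        io.write_json(persist, outdir / "attenuation_persistence.json")
        manifest["stages"]["attenuation"] = {
            "strata_counts": strata_res.strata_counts,
            "n_slope_rows": int(len(slopes)),
        }

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir()) if p.name != "manifest.json"
    }
    io.write_json(manifest, outdir / "manifest.json")
    return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def dataclasses_replace(cfg, **kw):
    import dataclasses

    return dataclasses.replace(cfg, **kw)


def demo_config(outdir: str = "ewaskit_demo", seed: int = 0) -> PipelineConfig:
    """Small single-arm configuration that completes in minutes."""
    from .simulate import SimulationConfig

    sim = SimulationConfig(
        n_probes=2_000, n_promoters=200, n_markers_per_type=20,
        design="single", n_treated=120, n_untreated=80,
        frac_causal_probes=0.02, frac_causal_promoters=0.05,
        batch_count=3, n_lump_probes=40, seed=seed,
    )
    return PipelineConfig(
        seed=seed, simulation=sim, n_perm_genes=200, n_perm_labels=50,
        n_gene_sets=30, n_enriched_sets=4, gene_set_size_range=(10, 20),
        outdir=outdir,
    )


def generate_fixtures(seed: int, outdir: str | Path) -> dict:
    """Write the small demo bundle (beta, detection-p, sheet, annotation,
    gene sets, truth) used by examples and the test suite."""
    cfg = demo_config(outdir=str(outdir), seed=seed)
    cfg = dataclasses_replace(
        cfg,
        simulation=dataclasses_replace(
            cfg.simulation, n_probes=600, n_promoters=80,
            n_treated=60, n_untreated=40, n_markers_per_type=12,
        ),
    )
    cohort = simulate_cohort(cfg.simulation)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_matrix(cohort.beta, out / "beta_raw.tsv")
    io.write_matrix(cohort.detection_p, out / "detection_p.tsv")
    io.write_sample_sheet(cohort.sheet, out / "sample_sheet.csv")
    io.write_annotation(cohort.annotation, out / "probe_annotation.bed.tsv")
    io.write_matrix(cohort.reference, out / "reference_methylome.tsv")
    gene_sets = make_gene_sets(
        cohort.truth, cohort.annotation, n_sets=cfg.n_gene_sets,
        set_size_range=cfg.gene_set_size_range,
        n_enriched=cfg.n_enriched_sets, seed=seed,
    )
    io.write_gmt(gene_sets, out / "gene_sets.gmt")
    io.write_json(cohort.truth.to_dict(), out / "truth.json")
    return {p.name: _sha256(p) for p in sorted(out.iterdir())}
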