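"""Moderated linear models: designs, OLS, variance moderation, regions.

The moderated-t chain is cross-checked against values computed with the
R packages limma (lmFit / contrasts.fit / eBayes) on the same
deterministically generated fixtures; those reference numbers are
frozen below.
"""

import numpy as np
import pandas as pd
import pytest

from ewaskit import diffmeth


def _paired_sheet(n_subj, time, subj, extra=None):
    samples = [f"S{s}_{'post' if t else 'pre'}" for s, t in zip(subj, time)]
    d = pd.DataFrame(
        {
            "subject_id": [f"S{s}" for s in subj],
            "timepoint": ["post" if t else "pre" for t in time],
            "treated": [bool(t) for t in time],
        },
        index=samples,
    )
    if extra:
        for k, v in extra.items():
            d[k] = v
    return d


def _fixture_homoscedastic():
    """30 features x 6 pairs with a monocyte covariate (seed 42)."""
    rng = np.random.default_rng(42)
    n_subj, n_feat = 6, 30
    mono = rng.uniform(0.03, 0.12, size=2 * n_subj)
    subj = np.repeat(np.arange(n_subj), 2)
    time = np.tile([0, 1], n_subj)
    Y = rng.normal(0.5, 0.05, size=(n_feat, 2 * n_subj))
    Y[:5] += 0.08 * time
    sheet = _paired_sheet(n_subj, time, subj, {"mono": mono})
    beta = pd.DataFrame(Y, index=[f"f{i}" for i in range(n_feat)], columns=sheet.index)
    return beta, sheet


def _fixture_heteroscedastic():
    """40 features x 8 pairs with lognormal variance spread (seed 123)."""
    rng = np.random.default_rng(123)
    n_subj, n_feat = 8, 40
    subj = np.repeat(np.arange(n_subj), 2)
    time = np.tile([0, 1], n_subj)
    sd = np.exp(rng.normal(np.log(0.04), 0.6, size=n_feat))
    Y = rng.normal(0.5, 1.0, size=(n_feat, 2 * n_subj)) * sd[:, None]
    Y[:6] += 0.1 * time
    sheet = _paired_sheet(n_subj, time, subj)
    beta = pd.DataFrame(Y, index=[f"f{i}" for i in range(n_feat)], columns=sheet.index)
    return beta, sheet


class TestBuildDesign:
    def test_minimal_paired_design_shape_and_contrast(self):
        sheet = _paired_sheet(2, [0, 1, 0, 1], [0, 0, 1, 1])
        design = diffmeth.build_design(sheet, "paired")
        assert design.X.shape == (4, 3)  # 2 time cols + 1 subject dummy
        assert design.rank == 3
        c = design.contrast
        assert c["time[post]"] == 1.0 and c["time[pre]"] == -1.0

    def test_contrast_recovers_mean_within_pair_difference(self):
        rng = np.random.default_rng(6)
        n_subj = 10
        subj = np.repeat(np.arange(n_subj), 2)
        time = np.tile([0, 1], n_subj)
        offsets = rng.normal(0, 2.0, n_subj)
        y = offsets[subj] + 0.3 * time + rng.normal(0, 1e-12, 2 * n_subj)
        sheet = _paired_sheet(n_subj, time, subj)
        beta = pd.DataFrame([y], index=["f0"], columns=sheet.index)
        design = diffmeth.build_design(sheet, "paired")
        fits = diffmeth.fit_feature_models(beta, design)
        assert fits.effect[0] == pytest.approx(0.3, abs=1e-9)

    def test_within_subject_shift_invariance(self):
        """Adding any per-subject constant to both timepoints leaves the
        paired contrast unchanged."""
        beta, sheet = _fixture_heteroscedastic()
        design = diffmeth.build_design(sheet, "paired")
        base = diffmeth.fit_feature_models(beta, design).effect
        rng = np.random.default_rng(0)
        shift = rng.normal(0, 5.0, sheet["subject_id"].nunique())
        lut = dict(zip(sorted(sheet["subject_id"].unique()), shift))
        shifted = beta + sheet["subject_id"].map(lut).to_numpy()[None, :]
        moved = diffmeth.fit_feature_models(shifted, design).effect
        assert np.allclose(base, moved, atol=1e-9)

    def test_unpaired_subject_rejected(self):
        sheet = _paired_sheet(2, [0, 1, 0, 1], [0, 0, 1, 1]).iloc[:-1]
        with pytest.raises(ValueError, match="unpaired"):
            diffmeth.build_design(sheet, "paired")

    def test_single_level_covariate_dropped_with_warning(self):
        sheet = _paired_sheet(3, [0, 1] * 3, np.repeat(np.arange(3), 2))
        sheet["batch"] = "B1"
        with pytest.warns(UserWarning, match="single level"):
            design = diffmeth.build_design(sheet, "paired", adjust=["batch"])
        assert not any(c.startswith("batch") for c in design.X.columns)

    def test_collinear_covariates_named(self):
        sheet = _paired_sheet(3, [0, 1] * 3, np.repeat(np.arange(3), 2))
        sheet["dup"] = sheet["treated"].astype(float)
        with pytest.raises(ValueError, match="dup"):
            diffmeth.build_design(sheet, "paired", adjust=["dup"])

    def test_single_mode_contrast(self):
        sheet = pd.DataFrame(
            {"treated": [True, False, True, False], "subject_id": list("abcd"),
             "timepoint": "single"},
            index=[f"s{i}" for i in range(4)],
        )
        design = diffmeth.build_design(sheet, "single")
        assert design.contrast["chemo[yes]"] == 1.0
        assert design.contrast["chemo[no]"] == -1.0


class TestFeatureFits:
    def test_matches_generic_lstsq_solver(self):
        rng = np.random.default_rng(31)
        n, p, n_feat = 16, 4, 20
        X = rng.normal(size=(n, p))
        Y = rng.normal(size=(n_feat, n))
        Xdf = pd.DataFrame(X, index=[f"s{i}" for i in range(n)],
                           columns=[f"c{j}" for j in range(p)])
        c = pd.Series([1.0, -1.0, 0.0, 0.0], index=Xdf.columns)
        design = diffmeth.DesignMatrix(X=Xdf, contrast=c)
        beta = pd.DataFrame(Y, index=[f"f{i}" for i in range(n_feat)],
                            columns=Xdf.index)
        fits = diffmeth.fit_feature_models(beta, design)
        for i in range(n_feat):
            coef, res, *_ = np.linalg.lstsq(X, Y[i], rcond=None)
            assert fits.effect[i] == pytest.approx(coef[0] - coef[1], abs=1e-10)
            assert fits.s2[i] == pytest.approx(float(res[0]) / (n - p), abs=1e-10)

    def test_feature_equal_to_design_column_has_zero_residual(self):
        sheet = _paired_sheet(4, [0, 1] * 4, np.repeat(np.arange(4), 2))
        design = diffmeth.build_design(sheet, "paired")
        y = design.X["time[post]"].to_numpy()
        beta = pd.DataFrame([y], index=["f0"], columns=sheet.index)
        fits = diffmeth.fit_feature_models(beta, design)
        assert fits.s2[0] == pytest.approx(0.0, abs=1e-20)

    def test_simple_regression_formula(self):
        rng = np.random.default_rng(77)
        x = rng.normal(size=12)
        y = 2.0 + 0.7 * x + rng.normal(0, 0.1, 12)
        X = pd.DataFrame({"intercept": np.ones(12), "x": x},
                         index=[f"s{i}" for i in range(12)])
        design = diffmeth.DesignMatrix(
            X=X, contrast=pd.Series([0.0, 1.0], index=X.columns)
        )
        beta = pd.DataFrame([y], index=["f0"], columns=X.index)
        fits = diffmeth.fit_feature_models(beta, design)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert fits.effect[0] == pytest.approx(slope, abs=1e-12)

    def test_zero_residual_df_rejected(self):
        X = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("xyz"))
        design = diffmeth.DesignMatrix(
            X=X, contrast=pd.Series([1.0, -1.0, 0.0], index=X.columns)
        )
        beta = pd.DataFrame(np.random.default_rng(0).random((2, 3)),
                            index=["f0", "f1"], columns=X.index)
        with pytest.raises(ValueError, match="degrees of freedom"):
            diffmeth.fit_feature_models(beta, design)


class TestEbayesAgainstLimma:
    """Frozen reference values computed with R limma on the same fixtures."""

    def test_homoscedastic_fixture_pooling_limit(self):
        beta, sheet = _fixture_homoscedastic()
        design = diffmeth.build_design(sheet, "paired", extra_numeric=sheet[["mono"]])
        res = diffmeth.ebayes_moderate(diffmeth.fit_feature_models(beta, design))
        assert res.attrs["d0"] == np.inf
        assert res.attrs["s0_2"] == pytest.approx(0.002271231344, rel=1e-9)
        expected = {
            "f0": (0.056814035349, 1.8373870838, 0.068626791126),
            "f3": (0.097356458473, 3.1485441621, 0.002070735964),
            "f7": (0.010687073831, 0.3456239519, 0.730230500321),
        }
        for f, (coef, t, p) in expected.items():
            assert res.at[f, "effect"] == pytest.approx(coef, rel=1e-9)
            assert res.at[f, "t"] == pytest.approx(t, rel=1e-8)
            assert res.at[f, "p"] == pytest.approx(p, rel=1e-8)

    def test_heteroscedastic_fixture_finite_prior(self):
        beta, sheet = _fixture_heteroscedastic()
        design = diffmeth.build_design(sheet, "paired")
        res = diffmeth.ebayes_moderate(diffmeth.fit_feature_models(beta, design))
        assert res.attrs["d0"] == pytest.approx(2.50878561834, rel=1e-8)
        assert res.attrs["s0_2"] == pytest.approx(0.00135383980092, rel=1e-8)
        expected = {
            "f0": (6.57656022936, 7.91630768377e-05),
            "f6": (-0.00840304435172, 0.993469091441),
            "f19": (1.02036870536, 0.332811747126),
            "f39": (1.30498535792, 0.22259310574),
        }
        for f, (t, p) in expected.items():
            assert res.at[f, "t"] == pytest.approx(t, rel=1e-8)
            assert res.at[f, "p"] == pytest.approx(p, rel=1e-8)


class TestEbayesLimits:
    def test_homogeneous_variances_reduce_to_ordinary_t(self):
        """When every feature has the same s2 the prior carries no
        information and the moderated t equals the ordinary t."""
        rng = np.random.default_rng(55)
        n_subj = 8
        subj = np.repeat(np.arange(n_subj), 2)
        time = np.tile([0, 1], n_subj)
        sheet = _paired_sheet(n_subj, time, subj)
        resid = rng.normal(0, 1.0, 2 * n_subj)
        resid -= resid.mean()
        Y = np.vstack([resid * s for s in (0.02,) * 25])  # identical shape
        offs = rng.normal(0, 0.05, 25)
        Y = Y + offs[:, None] * time[None, :]
        beta = pd.DataFrame(Y, index=[f"f{i}" for i in range(25)], columns=sheet.index)
        design = diffmeth.build_design(sheet, "paired")
        fits = diffmeth.fit_feature_models(beta, design)
        res = diffmeth.ebayes_moderate(fits)
        ordinary_t = fits.effect / (fits.stdev_unscaled * np.sqrt(fits.s2))
        assert np.allclose(res["t"], ordinary_t, rtol=1e-8)

    def test_forced_infinite_prior_pools_all_variances(self):
        beta, sheet = _fixture_homoscedastic()
        design = diffmeth.build_design(sheet, "paired", extra_numeric=sheet[["mono"]])
        res = diffmeth.ebayes_moderate(diffmeth.fit_feature_models(beta, design))
        assert res.attrs["d0"] == np.inf
        assert np.allclose(res["s2_post"], res.attrs["s0_2"])

    def test_null_moderated_pvalues_are_uniform(self):
        rng = np.random.default_rng(314)
        n_subj, n_feat = 20, 200
        subj = np.repeat(np.arange(n_subj), 2)
        time = np.tile([0, 1], n_subj)
        sd = np.exp(rng.normal(np.log(0.03), 0.4, size=n_feat))
        Y = rng.normal(0, 1.0, size=(n_feat, 2 * n_subj)) * sd[:, None]
        sheet = _paired_sheet(n_subj, time, subj)
        beta = pd.DataFrame(Y, index=[f"f{i}" for i in range(n_feat)],
                            columns=sheet.index)
        design = diffmeth.build_design(sheet, "paired")
        res = diffmeth.ebayes_moderate(diffmeth.fit_feature_models(beta, design))
        from scipy import stats as st

        ks = st.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01


class TestBonferroni:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (588_798, 8.49e-8),
            (41_207, 1.21e-6),
            (525_100, 9.52e-8),
            (40_271, 1.24e-6),
        ],
    )
    def test_reported_thresholds_to_three_significant_figures(self, n, expected):
        got = diffmeth.bonferroni_threshold(n, 0.05)
        assert float(f"{got:.3g}") == pytest.approx(expected, rel=1e-12)

    def test_single_test(self):
        assert diffmeth.bonferroni_threshold(1, 0.05) == 0.05

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            diffmeth.bonferroni_threshold(0)


class TestPromoterAggregation:
    @staticmethod
    def _regions(mapping):
        rows = [(p, prom, f"G_{prom}") for prom, probes in mapping.items()
                for p in probes]
        df = pd.DataFrame(rows, columns=["probe_id", "promoter_id", "gene_id"])
        return df.set_index("probe_id")

    def test_singleton_promoter_is_identity(self):
        beta = pd.DataFrame([[0.1, 0.9]], index=["p0"], columns=["a", "b"])
        agg = diffmeth.aggregate_promoters(beta, self._regions({"PR1": ["p0"]}))
        assert np.allclose(agg.loc["PR1"], beta.loc["p0"])

    def test_mean_of_two_probes(self):
        beta = pd.DataFrame([[0.2, 0.2], [0.4, 0.4]], index=["p0", "p1"],
                            columns=["a", "b"])
        agg = diffmeth.aggregate_promoters(beta, self._regions({"PR1": ["p0", "p1"]}))
        assert np.allclose(agg.loc["PR1"], 0.3)

    def test_commutes_with_sample_subsetting(self, paired_cohort):
        regions = diffmeth.build_region_map(paired_cohort.annotation)
        beta = paired_cohort.beta.fillna(0.5)
        sub = list(beta.columns[:10])
        a = diffmeth.aggregate_promoters(beta, regions)[sub]
        b = diffmeth.aggregate_promoters(beta[sub], regions)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_overlap_rejected(self):
        beta = pd.DataFrame([[0.5]], index=["px"], columns=["a"])
        with pytest.raises(ValueError):
            diffmeth.aggregate_promoters(beta, self._regions({"PR1": ["p0"]}))


class TestRegionsFromTss:
    def test_window_assignment_respects_strand(self):
        ann = pd.DataFrame(
            {"chrom": ["chr1"] * 4, "start": [900, 2100, 3100, 5000],
             "end": [902, 2102, 3102, 5002]},
            index=[f"p{i}" for i in range(4)],
        )
        tss = pd.DataFrame(
            [
                {"chrom": "chr1", "pos": 2000, "strand": "+",
                 "promoter_id": "PR+", "gene_id": "G1"},
                {"chrom": "chr1", "pos": 3000, "strand": "-",
                 "promoter_id": "PR-", "gene_id": "G2"},
            ]
        )
        regions = diffmeth.regions_from_tss(ann, tss)
        # + strand: [500, 2500) captures p0 and p1; - strand: [2500, 4500)
        assert regions.loc["p0", "promoter_id"] == "PR+"
        assert regions.loc["p1", "promoter_id"] == "PR+"
        assert regions.loc["p2", "promoter_id"] == "PR-"
        assert "p3" not in regions.index


class TestSignificanceCalls:
    @staticmethod
    def _results(effects, pvals):
        return pd.DataFrame({"effect": effects, "p": pvals},
                            index=[f"f{i}" for i in range(len(effects))])

    def test_intersection_empty_when_one_set_has_no_hits(self):
        a = diffmeth.call_significant(self._results([0.2, 0.1], [1e-9, 0.5]), 1e-6)
        b = diffmeth.call_significant(self._results([0.2, 0.1], [0.4, 0.5]), 1e-6)
        assert len(diffmeth.intersect_significant([a, b])) == 0

    def test_opposite_sign_excluded_from_intersection(self):
        a = diffmeth.call_significant(self._results([0.2], [1e-9]), 1e-6)
        b = diffmeth.call_significant(self._results([-0.2], [1e-9]), 1e-6)
        assert len(diffmeth.intersect_significant([a, b])) == 0

    def test_shared_planted_features_recovered_across_cohorts(self):
        """Three simulated paired cohorts sharing planted effects: the
        sign-concordant intersection contains the planted features."""
        from ewaskit.simulate import SimulationConfig, simulate_cohort

        results = []
        planted = None
        for seed in (101, 102, 103):
            cfg = SimulationConfig(
                n_probes=400, n_promoters=40, n_markers_per_type=8,
                design="paired", n_pairs=40, n_lump_probes=16,
                effect_size_delta=0.15, frac_missing=0.0,
                frac_elevated_detp=0.0, paired_post_time_range=(0.01, 0.05),
                causal_seed=77, seed=seed,
            )
            c = simulate_cohort(cfg)
            ids = {p for p, d in c.truth.true_delta_per_probe.items()}
            planted = ids if planted is None else planted & ids
            beta = c.beta
            design = diffmeth.build_design(c.sheet, "paired")
            res = diffmeth.ebayes_moderate(diffmeth.fit_feature_models(beta, design))
            thr = diffmeth.bonferroni_threshold(len(beta))
            results.append(diffmeth.call_significant(res, thr))
        hits = set(diffmeth.intersect_significant(results))
        assert planted
        assert len(hits & planted) >= 0.8 * len(planted)
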