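"""ANCOVA engine: outlier mask, design bookkeeping, partial F / eta^2,
bootstrap, BH-FDR, regional analysis, and the analysis roster."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from netcontrol.simulate import simulate_outcome_table
from netcontrol.stats import (
    DEFAULT_ROSTER,
    AncovaSpec,
    analysis_roster,
    bh_fdr,
    bootstrap_ci_eta,
    build_design,
    fit_ancova,
    partial_eta_from_F,
    remove_outliers_3sd,
    run_regional_analysis,
)
from netcontrol.stats import _batched_eta


class TestOutlierMask:
    def test_constant_vector_all_retained(self):
        assert remove_outliers_3sd([5.0] * 10).all()

    @pytest.mark.parametrize("v", [
        [0.0] * 9 + [100.0],   # at n=10 one extreme inflates the SD enough
        [0.0] * 99 + [100.0],  # to survive; at n=100 it is excluded
    ])
    def test_mask_matches_brute_force_mean_sd(self, v):
        mask = remove_outliers_3sd(v)
        mu, sd = np.mean(v), np.std(v, ddof=1)
        expected = np.abs(np.array(v) - mu) <= 3 * sd
        np.testing.assert_array_equal(mask, expected)
        assert mask[-1] == (len(v) == 10)

    def test_gaussian_exclusion_rate_matches_normal_tail(self):
        rng = np.random.default_rng(2024)
        v = rng.standard_normal(100_000)
        frac = 1.0 - remove_outliers_3sd(v).mean()
        assert frac == pytest.approx(2 * scipy.stats.norm.sf(3), abs=6e-4)

    def test_nan_handling(self):
        mask = remove_outliers_3sd([1.0, 2.0, np.nan, 3.0])
        assert not mask[2] and mask[[0, 1, 3]].all()


def _bounded_outcome_table(seed=0):
    """Cohort table whose outcomes are uniform, hence free of 3-SD outliers."""
    rng = np.random.default_rng(seed)
    table = simulate_outcome_table(820, 692, rng)
    for dep in ("wb_avg", "wb_modal"):
        table[dep] = rng.uniform(0.0, 1.0, len(table))
    return table


class TestDesign:
    def test_diagnosis_design_residual_df(self):
        # intercept + age + gender + site(2) + edge_count + diagnosis = 7
        table = _bounded_outcome_table()
        spec = AncovaSpec(
            dependent="wb_modal", effect="diagnosis",
            covariates=("age", "gender", "site", "edge_count"),
        )
        d = build_design(spec, table)
        assert d.n_used == 1512
        assert d.n_used - d.X_full.shape[1] == 1505

    def test_gender_design_residual_df_in_controls(self):
        table = _bounded_outcome_table()
        spec = AncovaSpec(
            dependent="wb_avg", effect="gender",
            covariates=("age", "site", "edge_count"),
            subset={"diagnosis": "HC"},
        )
        d = build_design(spec, table)
        assert d.n_used == 820
        assert d.n_used - d.X_full.shape[1] == 814

    def test_constant_effect_rejected(self):
        table = _bounded_outcome_table()
        table["flat"] = 1.0
        spec = AncovaSpec(dependent="wb_avg", effect="flat",
                          covariates=("age",))
        with pytest.raises(ValueError, match="constant"):
            build_design(spec, table)

    def test_rank_deficient_design_rejected(self):
        table = _bounded_outcome_table()
        table["age_copy"] = table["age"]
        spec = AncovaSpec(dependent="wb_avg", effect="diagnosis",
                          covariates=("age", "age_copy"))
        with pytest.raises(ValueError, match="rank"):
            build_design(spec, table)

    def test_listwise_deletion_counted(self):
        table = _bounded_outcome_table()
        table.loc[table.index[:25], "age"] = np.nan
        spec = AncovaSpec(dependent="wb_avg", effect="diagnosis",
                          covariates=("age",))
        d = build_design(spec, table)
        assert d.n_missing_dropped == 25
        assert d.n_used == 1512 - 25

    def test_effect_in_covariates_rejected(self):
        with pytest.raises(ValueError):
            AncovaSpec(dependent="y", effect="age", covariates=("age",))


class TestPartialEta:
    def test_printed_diagnosis_effect(self):
        assert partial_eta_from_F(7.96, 1, 1505) == pytest.approx(
            0.005261, abs=3e-5
        )

    def test_zero_F(self):
        assert partial_eta_from_F(0.0, 1, 100) == 0.0

    @pytest.mark.parametrize("eta, df2, F_printed", [
        (0.005261, 1505, 7.96),   # diagnosis, modal
        (0.029292, 811, 24.47),   # age in controls, average
    ])
    def test_inversion_recovers_printed_F(self, eta, df2, F_printed):
        F = df2 * eta / (1 * (1.0 - eta))
        assert round(F, 2) == pytest.approx(F_printed, abs=0.005)

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            partial_eta_from_F(1.0, 0, 10)


class TestFitAncova:
    def test_algebraic_identity_with_own_outputs(self):
        table = simulate_outcome_table(150, 150, np.random.default_rng(5),
                                       effect_sizes={"diagnosis": 0.3})
        spec = AncovaSpec(dependent="wb_avg", effect="diagnosis",
                          covariates=("age", "gender", "site", "edge_count"),
                          n_boot=0)
        r = fit_ancova(spec, table)
        assert r.partial_eta_sq == pytest.approx(
            partial_eta_from_F(r.F, r.df1, r.df2), abs=1e-12
        )
        # inversion of the eta formula recovers F
        back = r.df2 * r.partial_eta_sq / (r.df1 * (1 - r.partial_eta_sq))
        assert back == pytest.approx(r.F, abs=1e-10)

    def test_agrees_with_pingouin_ancova(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        table = simulate_outcome_table(120, 120, rng,
                                       effect_sizes={"diagnosis": 0.4})
        table = table[remove_outliers_3sd(table["wb_modal"])]
        spec = AncovaSpec(dependent="wb_modal", effect="diagnosis",
                          covariates=("age", "edge_count"), n_boot=0)
        r = fit_ancova(spec, table)
        pg = pingouin.ancova(data=table.reset_index(), dv="wb_modal",
                             between="diagnosis", covar=["age", "edge_count"])
        row = pg.set_index("Source").loc["diagnosis"]
        pcol = "p_unc" if "p_unc" in pg.columns else "p-unc"
        assert r.F == pytest.approx(row["F"], rel=1e-9)
        assert r.p == pytest.approx(row[pcol], rel=1e-9)
        assert r.partial_eta_sq == pytest.approx(row["np2"], rel=1e-6)

    def test_three_level_categorical_effect_df(self):
        table = simulate_outcome_table(0, 300, np.random.default_rng(4))
        spec = AncovaSpec(dependent="wb_avg", effect="remission",
                          covariates=("age", "gender"), n_boot=0)
        r = fit_ancova(spec, table)
        assert r.df1 == 2
        assert r.df2 == r.n_used - 5  # intercept + age + gender + 2 indicators


class TestBootstrap:
    def test_zero_width_ci_without_sampling_variability(self):
        # exact linear dependence: every resample estimates eta = 1
        rng = np.random.default_rng(1)
        n = 60
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        table = pd.DataFrame({"y": 2 * x + 3 * z, "x": x, "z": z})
        spec = AncovaSpec(dependent="y", effect="x", covariates=("z",),
                          n_boot=200)
        d = build_design(spec, table)
        lo, hi = bootstrap_ci_eta(d, n_boot=200, rng=rng)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_batched_eta_matches_statsmodels_resample_fits(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        table = simulate_outcome_table(80, 80, rng,
                                       effect_sizes={"diagnosis": 0.5})
        spec = AncovaSpec(dependent="wb_avg", effect="diagnosis",
                          covariates=("age", "gender", "edge_count"), n_boot=0)
        d = build_design(spec, table)
        idx = rng.integers(0, d.n_used, size=(20, d.n_used))
        etas, degen = _batched_eta(d.y, d.X_full, d.X_reduced, idx)
        assert not degen.any()
        for b in range(20):
            rows = idx[b]
            full = sm.OLS(d.y[rows], d.X_full[rows]).fit()
            red = sm.OLS(d.y[rows], d.X_reduced[rows]).fit()
            eta_ref = (red.ssr - full.ssr) / red.ssr
            assert etas[b] == pytest.approx(eta_ref, abs=1e-10)

    def test_fragile_design_errors_out(self):
        # a 3-level factor with one nearly-absent level degenerates resamples
        rng = np.random.default_rng(3)
        n = 40
        table = pd.DataFrame({
            "y": rng.normal(size=n),
            "site": ["site1"] * (n - 2) + ["site2", "site3"],
            "age": rng.normal(size=n),
        })
        spec = AncovaSpec(dependent="y", effect="site", covariates=("age",),
                          n_boot=100)
        d = build_design(spec, table)
        with pytest.raises(RuntimeError, match="degenerate"):
            bootstrap_ci_eta(d, n_boot=100, rng=rng)


class TestFdr:
    def test_single_p_reduces_to_raw_threshold(self):
        q, flags = bh_fdr([0.04], q=0.05)
        assert flags[0]

    def test_step_up_enumeration(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212,
             0.216]
        _, flags = bh_fdr(p, q=0.05)
        # brute-force step-up: largest k with p_(k) <= k*q/m; here
        # p_(2)=0.008 <= 0.010 but p_(5)=0.042 > 0.025, so exactly 2 pass
        m = len(p)
        k_star = max(
            k for k in range(1, m + 1) if sorted(p)[k - 1] <= k * 0.05 / m
        )
        assert flags.sum() == k_star == 2
        assert list(flags) == [True] * 2 + [False] * 8

    def test_all_unity_none_significant(self):
        _, flags = bh_fdr([1.0] * 8)
        assert not flags.any()

    def test_superset_of_bonferroni(self):
        rng = np.random.default_rng(77)
        p = rng.uniform(0, 0.2, 50)
        _, bh_flags = bh_fdr(p, q=0.05)
        bonf = p <= 0.05 / len(p)
        assert np.all(bh_flags[bonf])

    def test_missing_values_excluded(self):
        q, flags = bh_fdr([0.01, np.nan, 0.8])
        assert np.isnan(q[1]) and not flags[1]
        assert flags[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_flags_monotone_in_raw_p(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=30)
        _, flags = bh_fdr(p)
        if flags.any():
            assert p[flags].max() <= p[~flags].min() or not (~flags).any()


class TestRegional:
    def _node_table(self, rng, n=300, n_nodes=12, planted=(2, 7), beta=0.8):
        table = simulate_outcome_table(n // 2, n - n // 2, rng)
        d = (table["diagnosis"] == "MDD").to_numpy(float)
        for i in range(n_nodes):
            y = rng.normal(size=n)
            if i in planted:
                y = y + beta * d
            table[f"avg_ctrl_r{i}"] = y
        return table

    def test_identical_columns_identical_flags(self):
        rng = np.random.default_rng(9)
        table = self._node_table(rng, planted=())
        for i in range(12):
            table[f"avg_ctrl_r{i}"] = table["avg_ctrl_r0"]
        spec = AncovaSpec(dependent="avg_ctrl", effect="diagnosis",
                          covariates=("age", "edge_count"), n_boot=0)
        reg = run_regional_analysis(spec, table, [f"r{i}" for i in range(12)])
        ps = [r.p for r in reg.results]
        assert np.allclose(ps, ps[0])
        assert reg.significant.all() or not reg.significant.any()

    def test_planted_nodes_survive_fdr(self):
        rng = np.random.default_rng(15)
        table = self._node_table(rng, planted=(2, 7), beta=0.9)
        spec = AncovaSpec(dependent="avg_ctrl", effect="diagnosis",
                          covariates=("age", "edge_count"), n_boot=0)
        labels = [f"r{i}" for i in range(12)]
        reg = run_regional_analysis(spec, table, labels)
        flagged = {l for l, s in zip(labels, reg.significant) if s}
        assert {"r2", "r7"} <= flagged

    def test_one_row_per_region_and_failures_nonfatal(self):
        rng = np.random.default_rng(2)
        table = self._node_table(rng, planted=())
        table["avg_ctrl_r3"] = np.nan  # this node cannot be fit
        spec = AncovaSpec(dependent="avg_ctrl", effect="diagnosis",
                          covariates=("age",), n_boot=0)
        labels = [f"r{i}" for i in range(12)]
        reg = run_regional_analysis(spec, table, labels)
        assert len(reg.results) == 12
        assert reg.results[3].error is not None
        assert np.isnan(reg.q_values[3])


class TestRoster:
    def test_diagnosis_spec(self):
        specs = {s.name: s for s in analysis_roster(["diagnosis"])}
        s = specs["diagnosis_all_wb_modal"]
        assert s.effect == "diagnosis"
        assert s.covariates == ("age", "gender", "site", "edge_count")
        assert s.subset is None

    def test_prs_spec_adds_ancestry_and_medication(self):
        specs = {s.name: s for s in analysis_roster(["prs_mdd"])}
        s = specs["prs_mdd_MDD_wb_avg"]
        assert s.subset == {"diagnosis": "MDD"}
        assert set(("mds1", "mds2", "mds3", "medication_load")) <= set(
            s.covariates
        )

    def test_effect_never_among_covariates(self):
        for s in analysis_roster():
            assert s.effect not in s.covariates

    def test_misspelled_construct(self):
        with pytest.raises(KeyError, match="unknown construct"):
            analysis_roster(["diagnsis"])

    def test_full_roster_size(self):
        # 13 constructs, some in two subsets, each with two dependents
        specs = analysis_roster()
        assert len(specs) == 2 * sum(
            len(e["subsets"]) for e in DEFAULT_ROSTER.values()
        )
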