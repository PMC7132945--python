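"""Statistics layer: elementary operations against oracles, and the
cohort-level model."""

import time

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, stats as sps

import commissura as cm
from commissura.stats import (StructureCognitionModel, _log_likelihood_ratio,
                              _stretched_beta, correlation_bf10, holm_adjust)
from commissura.synthetic import CohortSpec


class TestIcvAdjust:
    def test_zero_slope_leaves_input_unchanged(self):
        icv = np.array([1.0, 2.0, 3.0, 4.0, 5.0]) * 1e6
        measure = np.array([2.0, 1.0, 3.0, 1.0, 2.0])
        measure = measure - np.polyfit(icv, measure, 1)[0] * (icv - icv.mean())
        np.testing.assert_allclose(cm.icv_adjust(measure, icv), measure,
                                   atol=1e-9)

    def test_subject_at_mean_icv_unchanged(self):
        rng = np.random.default_rng(1)
        icv = rng.normal(1.5e6, 2e5, 20)
        # setting icv[7] to the mean of the others makes it the overall mean
        icv[7] = (icv.sum() - icv[7]) / 19.0
        measure = rng.normal(5000, 400, 20) + 1e-3 * icv
        adj = cm.icv_adjust(measure, icv)
        assert adj[7] == pytest.approx(measure[7], rel=1e-6)

    def test_residual_orthogonality(self):
        t = cm.make_cohort(CohortSpec(n_subjects=95, seed=6))
        adj = cm.icv_adjust(t["hippocampus"].to_numpy(), t["icv"].to_numpy())
        r = np.corrcoef(adj, t["icv"])[0, 1]
        assert abs(r) < 1e-10
        assert adj.mean() == pytest.approx(t["hippocampus"].mean())

    def test_constant_icv_rejected(self):
        with pytest.raises(cm.ValidationError):
            cm.icv_adjust(np.arange(5.0), np.full(5, 2.0))


class TestPearsonBootstrap:
    def test_collinear_gives_unit_r_and_degenerate_ci(self):
        x = np.arange(10.0)
        res = cm.pearson_bootstrap(x, 2 * x + 1, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1.0) and res.ci_high == pytest.approx(1.0)

    def test_constructed_orthogonal_r_zero(self):
        x = np.r_[np.ones(5), -np.ones(5)]
        y = np.r_[1.0, -1, 1, -1, 0, 1, -1, 1, -1, 0]
        assert abs(x @ (y - y.mean())) < 1e-12
        res = cm.pearson_bootstrap(x, y, seed=0)
        assert res.r == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal((2, 40))
        a = cm.pearson_bootstrap(x, y, seed=9)
        b = cm.pearson_bootstrap(x, y, seed=9)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_zero_variance_rejected(self):
        with pytest.raises(cm.ValidationError):
            cm.pearson_bootstrap(np.ones(10), np.arange(10.0))

    def test_bca_flag_gives_sane_interval(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal(60)
        y = 0.5 * x + rng.standard_normal(60)
        res = cm.pearson_bootstrap(x, y, n_boot=500, seed=3, ci_method="bca")
        assert -1 <= res.ci_low < res.r < res.ci_high <= 1
        with pytest.raises(cm.ValidationError):
            cm.pearson_bootstrap(x, y, ci_method="jackknife")


class TestSpearman:
    def test_monotone_nonlinear_is_one(self):
        x = np.linspace(0, 3, 12)
        rho, _ = cm.spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho_rev, _ = cm.spearman(x, np.exp(x)[::-1])
        assert rho_rev == pytest.approx(-1.0)

    def test_tied_ranks_match_average_rank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0])

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0  # average of 1-based ranks
                i = j
            return ranks

        expected = np.corrcoef(avg_ranks(x), avg_ranks(y))[0, 1]
        rho, _ = cm.spearman(x, y)
        assert rho == pytest.approx(expected, rel=1e-12)


class TestHolm:
    def test_hand_stepped_example(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04, 0.03], m=3),
                                   [0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.2], m=1), [0.2])

    def test_family_larger_than_tests(self):
        # only the smallest members of an m=6 family re-examined
        np.testing.assert_allclose(holm_adjust([0.005, 0.02], m=6),
                                   [0.03, 0.1])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_dominated_by_bonferroni_and_valid(self, ps):
        adj = holm_adjust(ps)
        m = len(ps)
        assert np.all(adj <= np.minimum(1.0, m * np.asarray(ps)) + 1e-12)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)

    def test_agrees_with_statsmodels_when_family_complete(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(4)
        ps = rng.uniform(0, 1, 9)
        _, expected, _, _ = multipletests(ps, method="holm")
        np.testing.assert_allclose(holm_adjust(ps), expected, rtol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(cm.ValidationError):
            holm_adjust([0.5, 1.2])


class TestSteigerAndCohensQ:
    def test_equal_correlations_give_zero(self):
        for r12 in (-0.5, 0.0, 0.7):
            res = cm.steiger_dependent_z(0.4, 0.4, r12, 50)
            assert res.z == 0.0 and res.q == 0.0

    @pytest.mark.parametrize("r1,r2,expected_q", [
        (-0.269, 0.100, 0.376),
        (-0.269, -0.072, 0.204),
        (-0.269, -0.047, 0.229),
    ])
    def test_cohens_q_printed_pairs(self, r1, r2, expected_q):
        assert abs(cm.cohens_q(r1, r2)) == pytest.approx(expected_q, abs=5e-4)

    def test_textbook_formula_oracle(self):
        """Independent step-by-step evaluation of the pooled-r Z1* statistic."""
        r1, r2, r12, n = 0.5, 0.3, 0.4, 100
        # oracle path: explicit covariance of Fisher z's with pooled r
        rbar = 0.5 * (r1 + r2)
        cov = (r12 * (1.0 - rbar**2 - rbar**2)
               - 0.5 * rbar**2 * (1.0 - rbar**2 - rbar**2 - r12**2)) \
            / ((1.0 - rbar**2) ** 2)
        z_oracle = (np.arctanh(r1) - np.arctanh(r2)) * np.sqrt(
            (n - 3) / (2.0 * (1.0 - cov)))
        res = cm.steiger_dependent_z(r1, r2, r12, n)
        assert res.z == pytest.approx(z_oracle, abs=1e-10)
        assert res.p == pytest.approx(sps.norm.sf(abs(z_oracle)), abs=1e-12)

    def test_two_tailed_doubles_p(self):
        one = cm.steiger_dependent_z(0.5, 0.2, 0.3, 60, tail="one")
        two = cm.steiger_dependent_z(0.5, 0.2, 0.3, 60, tail="two")
        assert two.p == pytest.approx(2 * one.p)

    def test_input_validation(self):
        with pytest.raises(cm.ValidationError):
            cm.steiger_dependent_z(1.0, 0.3, 0.2, 50)
        with pytest.raises(cm.ValidationError):
            cm.steiger_dependent_z(0.5, 0.3, 0.2, 5)
        with pytest.raises(cm.ValidationError):
            cm.cohens_q(0.5, -1.0)


class TestBayesFactor:
    def test_null_r_large_n_supports_null(self):
        b_small = correlation_bf10(0.0, 20)
        b_large = correlation_bf10(0.0, 500)
        assert b_large.bf10 < b_small.bf10 < 1.0

    def test_nonzero_r_evidence_grows_with_n(self):
        b_small = correlation_bf10(0.4, 30)
        b_large = correlation_bf10(0.4, 120)
        assert b_large.bf10 > b_small.bf10 > 1.0

    def test_credible_interval_inside_unit_disc(self):
        res = correlation_bf10(-0.269, 95)
        assert -1 < res.ci_low < res.ci_high < 1
        assert res.ci_low < -0.269 < res.ci_high

    @pytest.mark.parametrize("r,n", [(-0.269, 95), (0.0, 50), (0.35, 40),
                                     (-0.6, 25), (0.15, 200)])
    def test_adaptive_quadrature_agrees_with_grid_oracle(self, r, n):
        res = correlation_bf10(r, n)
        grid = np.linspace(-1 + 1e-7, 1 - 1e-7, 200_001)
        vals = np.exp(_log_likelihood_ratio(grid, r, n)) * _stretched_beta(grid, 1.0)
        oracle = integrate.trapezoid(vals, grid)
        assert res.bf10 == pytest.approx(oracle, rel=1e-6)

    def test_input_validation(self):
        with pytest.raises(cm.ValidationError):
            correlation_bf10(1.0, 95)
        with pytest.raises(cm.ValidationError):
            correlation_bf10(0.3, 4)


class TestStructureCognitionModel:
    def test_planted_effect_detected_and_localized(self):
        """With a planted MD-memory effect of r = -0.4 in one tract only, the
        Holm-corrected family flags exactly that association in >= 80% of
        simulated cohorts."""
        hits = 0
        n_rep = 1000
        for i, ss in enumerate(np.random.SeedSequence(101).spawn(n_rep)):
            cohort = cm.make_cohort(CohortSpec(
                n_subjects=95, true_corr_md_memory=-0.4,
                seed=int(ss.generate_state(1)[0] % 2**31)))
            res = StructureCognitionModel(cohort, volumes=()).fit(
                n_boot=0, seed=i, sensitivity=False)
            sig = res.significant
            exact = (len(sig) == 1
                     and sig.iloc[0]["tract"] == "dhc"
                     and sig.iloc[0]["metric"] == "md"
                     and sig.iloc[0]["task"] == "cpwm")
            hits += exact
        assert hits / n_rep >= 0.8

    def test_smoke_full_pipeline_under_ten_seconds(self):
        cohort = cm.make_cohort(CohortSpec(n_subjects=95,
                                           true_corr_md_memory=-0.5, seed=42))
        t0 = time.time()
        res = cm.run_structure_cognition_analysis(cohort, seed=0)
        elapsed = time.time() - t0
        assert elapsed < 10.0
        assert len(res.tract_correlations) == 12   # 2 tracts x 2 metrics x 3 tasks
        assert res.volume_correlations is not None
        assert len(res.volume_correlations) == 15
        assert (res.volume_correlations["m"] == 15).all()
        text = res.summary()
        assert "Tract correlations" in text
        assert "complete-case subjects: 95" in text

    def test_significant_association_triggers_comparison_and_sensitivity(self):
        cohort = cm.make_cohort(CohortSpec(n_subjects=95,
                                           true_corr_md_memory=-0.5, seed=42))
        res = StructureCognitionModel(cohort).fit(seed=1)
        sig = res.significant
        assert len(sig) >= 1
        assert len(res.comparisons) >= 1
        row = res.comparisons.iloc[0]
        assert row["q_abs"] == pytest.approx(
            abs(cm.cohens_q(row["r1"], row["r2"])), abs=1e-12)
        sens = res.sensitivity["per_association"]
        assert len(sens) == len(sig)
        assert {"spearman_rho", "bf10", "n_outliers"} <= set(sens.columns)

    def test_missing_column_is_schema_error(self):
        cohort = cm.make_cohort(CohortSpec(n_subjects=20, seed=3))
        with pytest.raises(cm.ValidationError, match="lacks column"):
            StructureCognitionModel(cohort.drop(columns=["ac_md"]))

    def test_complete_case_restriction(self):
        cohort = cm.make_cohort(CohortSpec(n_subjects=30, seed=3))
        cohort.loc[3, "ac_md"] = np.nan
        cohort.loc[7, "cpwm"] = np.nan
        model = StructureCognitionModel(cohort)
        assert model.n_complete == 28

    def test_fit_deterministic_under_seed(self):
        cohort = cm.make_cohort(CohortSpec(n_subjects=40, seed=11))
        a = StructureCognitionModel(cohort).fit(seed=5, sensitivity=False)
        b = StructureCognitionModel(cohort).fit(seed=5, sensitivity=False)
        pd.testing.assert_frame_equal(a.tract_correlations, b.tract_correlations)
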