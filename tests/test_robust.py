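import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from crossfluid import core_io, robust, synthetic
from crossfluid.errors import (
    DegenerateDesignError,
    InsufficientDataError,
    ParameterError,
    UndefinedCorrelationError,
)
from crossfluid.robust import RobustFit
from oracles import irls_huber_oracle, weighted_pearson_by_hand


def line_plus_outlier(n=10, seed=0):
    """y = x plus one gross outlier shifted by 100 standard deviations."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = x + 0.01 * rng.standard_normal(n)
    y = y.copy()
    y[-1] += 100 * y.std()
    return x, y


class TestHuberIrls:
    def test_noiseless_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        fit = robust.huber_irls(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert np.all(fit.weights == 1.0)
        assert fit.converged

    def test_outlier_downweighted(self):
        x, y = line_plus_outlier()
        fit = robust.huber_irls(x, y)
        assert fit.slope == pytest.approx(1.0, abs=0.05)
        assert fit.weights[-1] < 0.2

    def test_matches_independent_oracle(self):
        x, y = line_plus_outlier(n=15, seed=3)
        fit = robust.huber_irls(x, y, tol=1e-12, max_iter=500)
        a, b, w = irls_huber_oracle(x, y)
        assert fit.slope == pytest.approx(a, abs=1e-8)
        assert fit.intercept == pytest.approx(b, abs=1e-8)
        np.testing.assert_allclose(fit.weights, w, atol=1e-6)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            robust.huber_irls([1.0, 2.0], [1.0, 2.0])

    def test_constant_x(self):
        with pytest.raises(DegenerateDesignError):
            robust.huber_irls([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_nan_pairs_excluded(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, np.nan])
        y = np.array([1.0, 3.0, 5.0, 7.0, 100.0])
        fit = robust.huber_irls(x, y)
        assert fit.n_obs == 4
        assert fit.slope == pytest.approx(2.0, abs=1e-10)

    def test_equals_ols_when_no_large_residuals(self, rng):
        # all standardized residuals below the tuning constant -> pure OLS
        x = np.linspace(0, 1, 25)
        y = 3 * x + 1 + 0.05 * np.sin(np.arange(25))
        fit = robust.huber_irls(x, y)
        slope_ols, intercept_ols = np.polyfit(x, y, 1)
        if np.all(np.abs(fit.residuals(x, y)) / fit.scale <= robust.DEFAULT_TUNING):
            assert fit.slope == pytest.approx(slope_ols, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept_ols, abs=1e-10)
            assert np.all(fit.weights == 1.0)

    def test_breakdown_demo(self):
        # one gross outlier among n=20: OLS slope moves > 0.3, Huber < 0.05
        rng = np.random.default_rng(2024)
        x = rng.standard_normal(20)
        y = x + 0.05 * rng.standard_normal(20)
        slope_ols_clean = np.polyfit(x, y, 1)[0]
        slope_h_clean = robust.huber_irls(x, y).slope
        y2 = y.copy()
        y2[np.argmax(x)] -= 20.0
        slope_ols = np.polyfit(x, y2, 1)[0]
        slope_h = robust.huber_irls(x, y2).slope
        assert abs(slope_ols - slope_ols_clean) > 0.3
        assert abs(slope_h - slope_h_clean) < 0.05


class TestWeightedCorrelation:
    def test_unit_weights_reduce_to_pearson(self, rng):
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        r_w = robust.weighted_correlation(x, y, np.ones(40))
        r_p, _ = stats.pearsonr(x, y)
        assert r_w == pytest.approx(r_p, abs=1e-12)

    def test_self_correlation(self, rng):
        x = rng.standard_normal(20)
        w = rng.uniform(0.1, 1.0, 20)
        assert robust.weighted_correlation(x, x, w) == pytest.approx(1.0, abs=1e-12)

    def test_huber_weights_rescue_outlier_case(self):
        x, y = line_plus_outlier(seed=2)
        fit = robust.huber_irls(x, y)
        r_w = robust.weighted_correlation(x, y, fit.weights)
        r_plain, _ = stats.pearsonr(x, y)
        assert r_w >= 0.95
        assert r_plain < 0.8

    def test_matches_hand_formula(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        w = rng.uniform(0, 1, 30)
        assert robust.weighted_correlation(x, y, w) == pytest.approx(
            weighted_pearson_by_hand(x, y, w), abs=1e-12
        )

    def test_zero_variance_errors(self):
        with pytest.raises(UndefinedCorrelationError):
            robust.weighted_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1, 1, 1])

    def test_negative_weights_rejected(self):
        with pytest.raises(ParameterError):
            robust.weighted_correlation([1.0, 2.0], [1.0, 2.0], [1.0, -1.0])

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_bounded_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        w = rng.uniform(0.01, 1.0, 12)
        r_xy = robust.weighted_correlation(x, y, w)
        r_yx = robust.weighted_correlation(y, x, w)
        assert -1.0 <= r_xy <= 1.0
        assert r_xy == pytest.approx(r_yx, abs=1e-12)


class TestCorrelationPvalue:
    def test_zero_r(self):
        assert robust.correlation_pvalue(0.0, 20) == pytest.approx(1.0)

    def test_frozen_case(self):
        # oracle: t = 0.9 * sqrt(7 / 0.19) = 5.462793 on 7 df; tail verified
        # by numerical integration of the t density
        assert robust.correlation_pvalue(0.9, 9) == pytest.approx(9.430623e-4, rel=1e-5)

    def test_exact_r_one(self):
        assert robust.correlation_pvalue(1.0, 10) == 0.0

    def test_monotone_in_abs_r(self):
        ps = [robust.correlation_pvalue(r, 15) for r in np.linspace(0, 0.99, 25)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestHuberSlopePvalue:
    def test_strong_signal_small_p(self):
        x = np.linspace(0, 1, 20)
        y = 2 * x + 0.01 * np.sin(np.arange(20))
        fit = robust.huber_irls(x, y)
        assert robust.huber_slope_pvalue(fit, x, y) < 1e-8

    def test_null_p_not_tiny(self, rng):
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        fit = robust.huber_irls(x, y)
        assert robust.huber_slope_pvalue(fit, x, y) > 1e-4


class TestCorrelateMetabolite:
    def test_record_fields(self, default_paired):
        paired, _ = default_paired
        rec = robust.correlate_metabolite(paired, paired.metabolites[0], "combined")
        assert rec.valid and rec.n_obs == 31
        assert -1 <= rec.r_huber <= 1 and 0 < rec.p_huber <= 1

    def test_invalid_scope(self, default_paired):
        paired, _ = default_paired
        with pytest.raises(ParameterError):
            robust.correlate_metabolite(paired, paired.metabolites[0], "everyone")

    def test_planted_control_correlation_monte_carlo(self):
        hits = 0
        n_seeds = 200
        rho = np.array([[0.0, 0.95]])
        for seed in range(n_seeds):
            cfg = synthetic.SimulationConfig(
                n_metabolites=1, n_replicates=1, rho_by_group=rho, seed=seed
            )
            ds, _ = synthetic.simulate_dataset(cfg)
            paired = core_io.build_paired_table(
                core_io.ln_transform(core_io.average_replicates(ds))
            )
            rec = robust.correlate_metabolite(paired, "M001", "controls")
            assert rec.n_obs == 11
            if 0.7 <= rec.r_huber <= 1.0:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_sign_recovery_of_group_difference(self, default_paired):
        paired, truth = default_paired
        agree = total = 0
        for j, m in enumerate(truth.metabolites):
            d_rho = truth.rho[j, 0] - truth.rho[j, 1]
            if abs(d_rho) < 0.5:
                continue
            r_pat = robust.correlate_metabolite(paired, m, "patients").r_huber
            r_ctrl = robust.correlate_metabolite(paired, m, "controls").r_huber
            total += 1
            if np.sign(r_pat - r_ctrl) == np.sign(d_rho):
                agree += 1
        assert total >= 17
        assert agree >= 0.9 * total


class TestScaleResiduals:
    def test_three_four_five(self):
        fit = RobustFit(0.0, 0.0, 1.0, np.ones(2), 2, 1, True)
        prof = robust.scale_residuals(
            fit, np.zeros(2), np.array([3.0, 4.0]), np.array(["glioma", "control"])
        )
        np.testing.assert_allclose(prof.scaled_residuals, [0.6, 0.8])
        assert (prof.scaled_residuals**2).sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_residuals_group_shares(self):
        n_pat, n_ctrl = 20, 11
        groups = np.array(["glioma"] * n_pat + ["control"] * n_ctrl)
        fit = RobustFit(0.0, 0.0, 1.0, np.ones(31), 31, 1, True)
        prof = robust.scale_residuals(fit, np.zeros(31), np.ones(31), groups)
        assert prof.group_share_patients == pytest.approx(20 / 31)
        assert prof.group_share_controls == pytest.approx(11 / 31)

    def test_zero_residuals_flagged(self):
        fit = RobustFit(1.0, 0.0, 1.0, np.ones(4), 4, 1, True)
        x = np.arange(4.0)
        prof = robust.scale_residuals(fit, x, x, np.array(["glioma"] * 2 + ["control"] * 2))
        assert prof.degenerate
        assert prof.group_share_patients == pytest.approx(0.5)

    def test_random_instance_matches_oracle(self, rng):
        x = rng.standard_normal(15)
        y = rng.standard_normal(15)
        groups = np.array(["glioma"] * 9 + ["control"] * 6)
        fit = robust.huber_irls(x, y)
        prof = robust.scale_residuals(fit, x, y, groups)
        e = y - (fit.slope * x + fit.intercept)
        scaled = e / np.sqrt((e**2).sum())
        np.testing.assert_allclose(prof.scaled_residuals, scaled, atol=1e-12)
        assert prof.group_share_patients == pytest.approx((scaled[:9] ** 2).sum())
        assert (prof.scaled_residuals**2).sum() == pytest.approx(1.0, abs=1e-9)
        assert prof.group_share_patients + prof.group_share_controls == pytest.approx(1.0)


class TestResidualShareMatrix:
    def test_per_metabolite_columns_unit_ss(self, default_paired):
        paired, _ = default_paired
        shares = robust.residual_share_matrix(paired, mode="per_metabolite")
        ss = np.nansum(shares**2, axis=0)
        ok = np.isfinite(ss) & (ss > 0)
        np.testing.assert_allclose(ss[ok], 1.0, atol=1e-9)

    def test_per_subject_rows_unit_ss(self, default_paired):
        paired, _ = default_paired
        shares = robust.residual_share_matrix(paired, mode="per_subject")
        ss = np.nansum(shares**2, axis=1)
        np.testing.assert_allclose(ss[ss > 0], 1.0, atol=1e-9)

    def test_unknown_mode(self, default_paired):
        paired, _ = default_paired
        with pytest.raises(ParameterError):
            robust.residual_share_matrix(paired, mode="sideways")


class TestMeanProfileCorrelation:
    def test_identity_profiles(self, default_paired):
        paired, _ = default_paired
        clone = core_io.PairedProfileTable(
            paired.subjects, paired.metabolites, paired.s_pl, paired.s_pl
        )
        assert robust.mean_profile_correlation(clone) == pytest.approx(1.0)

    def test_scopes_run(self, default_paired):
        paired, _ = default_paired
        for scope in robust.SCOPES:
            r = robust.mean_profile_correlation(paired, scope)
            assert -1.0 <= r <= 1.0
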