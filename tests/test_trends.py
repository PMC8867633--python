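import numpy as np
import pytest

import qitrend as q
from qitrend.errors import ValidationError
from qitrend.standardization import StandardizedPrevalences
from qitrend.trends import (
    TrendFit,
    acceleration_fit,
    fit_trend_model,
    five_year_trends,
    overall_linear_trend,
)


def _sp(p_hat, se=1e-6, years=None, regions=None):
    p_hat = np.asarray(p_hat, dtype=float)
    n_r, n_t = p_hat.shape
    return StandardizedPrevalences(
        regions=regions or [f"R{i}" for i in range(n_r)],
        years=np.arange(n_t, dtype=float) if years is None else np.asarray(years, float),
        p_hat=p_hat,
        se=np.full_like(p_hat, se),
        n_reference={},
    )


class TestFitTrendModel:
    def test_common_linear_trend_absorbed_into_year_effects(self):
        years = np.arange(10.0)
        p = np.tile(0.2 + 0.01 * years, (5, 1))
        fit = fit_trend_model(_sp(p))
        assert np.abs(fit.theta_tilde).max() < 1e-8
        assert fit.tau == pytest.approx(0.0, abs=1e-6)

    def test_two_region_slopes_obey_side_condition(self):
        years = np.arange(10.0)
        p = np.vstack([0.2 + 0.00 * years, 0.2 + 0.02 * years])
        fit = fit_trend_model(_sp(p))
        # deviations from the common mean slope 0.01 are -/+ 0.01
        assert fit.theta_tilde == pytest.approx([-0.01, 0.01], abs=1e-8)
        assert fit.theta_tilde.sum() == pytest.approx(0.0, abs=1e-10)

    def test_side_conditions_hold_numerically(self, small_panel):
        years = np.arange(8.0)
        rng = np.random.default_rng(3)
        p = rng.uniform(0.2, 0.4, (6, 8))
        fit = fit_trend_model(_sp(p, se=0.01))
        assert abs(fit.alpha_t.sum()) < 1e-8
        assert abs(fit.theta_tilde.sum()) < 1e-8

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValidationError):
            fit_trend_model(_sp(np.full((2, 2), 0.3), se=0.01))

    def test_constant_shift_moves_only_region_levels(self):
        years = np.arange(6.0)
        rng = np.random.default_rng(4)
        base = 0.3 + 0.002 * rng.normal(size=(4, 1)) * years + 0.01 * rng.random((4, 6))
        f1 = fit_trend_model(_sp(base))
        f2 = fit_trend_model(_sp(base + 0.05))
        assert np.allclose(f1.alpha_t, f2.alpha_t, atol=1e-8)
        assert np.allclose(f1.theta_tilde, f2.theta_tilde, atol=1e-8)
        assert np.allclose(f2.beta_r - f1.beta_r, 0.05, atol=1e-8)

    def test_common_added_slope_moves_only_year_effects(self):
        years = np.arange(6.0)
        rng = np.random.default_rng(5)
        base = 0.3 + 0.01 * rng.random((4, 6))
        f1 = fit_trend_model(_sp(base))
        f2 = fit_trend_model(_sp(base + 0.004 * years[None, :]))
        assert np.allclose(f1.theta_tilde, f2.theta_tilde, atol=1e-8)
        t1, _, _ = overall_linear_trend(f1.alpha_t, f1.years, f1.cov_alpha)
        t2, _, _ = overall_linear_trend(f2.alpha_t, f2.years, f2.cov_alpha)
        assert t2 - t1 == pytest.approx(0.004, abs=1e-8)

    def test_tau_recovery_in_simulation(self):
        true_tau = 0.01
        rng = np.random.default_rng(6)
        years = np.arange(10.0)
        base = rng.uniform(0.2, 0.4, 8)
        slopes = rng.normal(0, 0.002, 8)
        se = 0.008
        taus = []
        for rep in range(500):
            r2 = np.random.default_rng(rep)
            mean = base[:, None] + slopes[:, None] * years[None, :]
            y = mean + r2.normal(0, true_tau, mean.shape) + r2.normal(0, se, mean.shape)
            taus.append(fit_trend_model(_sp(y, se=se)).tau)
        assert np.mean(taus) == pytest.approx(true_tau, rel=0.15)


class TestOverallLinearTrend:
    def test_hand_example(self):
        theta, _, _ = overall_linear_trend(np.array([-1.0, 0.0, 1.0]), np.array([0, 1, 2]))
        assert theta == pytest.approx(1.0)

    def test_zero_alpha_gives_zero(self):
        theta, _, _ = overall_linear_trend(np.zeros(5), np.arange(5))
        assert theta == 0.0

    def test_matches_generic_ols(self):
        rng = np.random.default_rng(7)
        alpha = rng.normal(size=8)
        alpha -= alpha.mean()  # side condition
        years = np.arange(8.0)
        theta, _, _ = overall_linear_trend(alpha, years)
        slope = np.polyfit(years, alpha, 1)[0]
        assert theta == pytest.approx(slope, abs=1e-12)

    def test_single_year_rejected(self):
        with pytest.raises(ValidationError):
            overall_linear_trend(np.array([0.0]), np.array([3.0]))


class TestFiveYearTrends:
    def test_unit_conversion_arithmetic(self):
        # theta_tilde 0.004/yr + overall 0.002/yr -> 5*0.006 = 3.0 pp
        years = np.arange(3.0)
        fit = TrendFit(
            regions=["A", "B"],
            years=years,
            alpha_t=0.002 * (years - 1.0),
            beta_r=np.zeros(2),
            theta_tilde=np.array([0.004, -0.004]),
            tau=0.0,
            cov_alpha=np.zeros((3, 3)),
            cov_theta=np.diag([1e-6, 1e-6]),
            cov_alpha_theta=np.zeros((3, 2)),
            tau_method="reml",
        )
        te = five_year_trends(fit)
        assert te.theta_r[0] == pytest.approx(3.0, abs=1e-10)
        # zero covariance blocks: Var = 25 (Var(theta_tilde) + c'Var(alpha)c)
        assert te.se_r[0] == pytest.approx(500 * np.sqrt(1e-6), rel=1e-9)

    def test_noise_free_linear_scenario_recovers_common_slope(self):
        years = np.arange(10.0)
        p = np.tile(0.2 + 0.01 * years, (5, 1))
        te = five_year_trends(fit_trend_model(_sp(p)))
        assert np.allclose(te.theta_r, 5.0, atol=1e-8)  # 0.01/yr = 5 pp per 5 yrs

    def test_time_axis_scaling_equivariance(self):
        """Halving the slope over a doubled year axis keeps theta_r fixed."""
        years = np.arange(0.0, 10.0)
        rng = np.random.default_rng(8)
        slopes = rng.normal(0.01, 0.002, 4)
        p1 = 0.3 + slopes[:, None] * years[None, :]
        p2 = 0.3 + (slopes / 2)[:, None] * (2 * years)[None, :]
        te1 = five_year_trends(fit_trend_model(_sp(p1)))
        te2 = five_year_trends(fit_trend_model(_sp(p2, years=2 * years)))
        assert np.allclose(5 * slopes * 100, te1.theta_r, atol=1e-7)
        assert np.allclose(te1.theta_r / 2, te2.theta_r, atol=1e-7)


class TestAcceleration:
    def test_globally_linear_input_has_zero_kink(self):
        years = np.arange(10.0)
        rng = np.random.default_rng(9)
        slopes = rng.normal(0.005, 0.002, 5)
        p = 0.3 + slopes[:, None] * years[None, :]
        acc = acceleration_fit(_sp(p), "R0")
        assert acc.delta == pytest.approx(0.0, abs=1e-8)
        assert acc.knot == 4.5

    def test_recovers_mid_period_slope_change(self):
        years = np.arange(10.0)
        p = np.tile(0.3 + 0.004 * years, (5, 1))
        kink = 0.006
        p[0] = 0.3 + 0.004 * years + kink * np.maximum(years - 4.5, 0.0)
        acc = acceleration_fit(_sp(p), "R0")
        assert acc.delta == pytest.approx(500 * kink, abs=1e-6)
        assert acc.theta_late - acc.theta_early == pytest.approx(acc.delta, abs=1e-10)

    def test_too_short_period_rejected(self):
        p = np.full((3, 3), 0.3)
        with pytest.raises(ValidationError):
            acceleration_fit(_sp(p), "R0")


def test_per_region_regression_agrees_with_joint_model():
    """Sensitivity variant: per-region WLS slopes on a linear-profile
    scenario agree with the joint estimates within combined 2 SE."""
    rng = np.random.default_rng(10)
    years = np.arange(10.0)
    slopes = rng.normal(0.004, 0.002, 6)
    se = 0.004
    p = 0.3 + slopes[:, None] * years[None, :] + rng.normal(0, se, (6, 10))
    sp = _sp(p, se=se)
    te = five_year_trends(fit_trend_model(sp))
    for i in range(6):
        coef, cov = np.polyfit(years, p[i], 1, cov=True)
        alt = 500 * coef[0]
        alt_se = 500 * np.sqrt(cov[0, 0])
        joint, joint_se = te.theta_r[i], te.se_r[i]
        assert abs(alt - joint) < 2 * np.hypot(alt_se, joint_se) + 1e-9
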