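"""Apparent base temperature and thermal-time estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from budforce.estimation import (
    AccessionExclusion,
    ForcingTimeCourse,
    InsufficientTemperaturesError,
    RatePoint,
    ThermalTimeFit,
    bud_break_fraction,
    correlate,
    delta_method_cis,
    estimate_accession,
    fit_rate_response,
    fit_tb_theta_curve,
    hours_to_half,
)
from budforce.synthetic import MEASURED_CHAMBER_TEMPS_C

TEMPS = np.array(MEASURED_CHAMBER_TEMPS_C)


def course(obs, cum, n_initial=100, temp=15.9, acc="A"):
    return ForcingTimeCourse(acc, temp, np.asarray(obs), np.asarray(cum), n_initial)


def exact_points(tb, theta, temps=TEMPS):
    """Noise-free rate points from the linear rate-temperature model."""
    return [RatePoint(t, theta / (t - tb)) for t in temps]


def ols_oracle(x, y):
    """Normal-equations least squares, independent of the implementation."""
    X = np.column_stack([np.ones_like(x), x])
    b, m = np.linalg.solve(X.T @ X, X.T @ y)
    return m, b


class TestTimeCourseInvariants:
    def test_decreasing_counts_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            course([24, 48], [10, 5])

    def test_counts_above_initial_rejected(self):
        with pytest.raises(ValueError):
            course([24, 48], [10, 150], n_initial=100)

    def test_non_increasing_hours_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            course([48, 48], [0, 10])


class TestBudBreakFraction:
    def test_direct_ratio(self):
        f = bud_break_fraction(course([24, 48, 72], [10, 60, 100]))
        assert list(f) == pytest.approx([0.10, 0.60, 1.00])

    def test_all_zero_counts(self):
        f = bud_break_fraction(course([24, 48], [0, 0]))
        assert list(f) == [0.0, 0.0]

    def test_single_observation(self):
        assert bud_break_fraction(course([24], [50]))[0] == pytest.approx(0.5)


class TestHoursToHalf:
    def test_interpolates_first_bracketing_pair(self):
        # fractions 0.4 at 96 h and 0.6 at 120 h bracket 0.5 -> 108 h
        assert hours_to_half(course([96, 120], [40, 60])) == pytest.approx(108.0)

    def test_exact_hit_returns_observation_time(self):
        assert hours_to_half(course([48, 72, 96], [10, 50, 90])) == 72.0

    def test_plateau_below_half_is_absent(self):
        # mirrors accessions that never reached 0.5 in any treatment
        assert hours_to_half(course([24, 48, 72], [30, 45, 45])) is None

    def test_first_observation_above_half_uses_origin(self):
        # implicit (0 h, fraction 0) lower bracket
        assert hours_to_half(course([100], [80])) == pytest.approx(62.5)

    def test_monotone_under_uniformly_faster_break(self):
        slow = course([96, 120, 144], [20, 55, 80])
        fast = course([48, 72, 96], [20, 55, 80])  # same fractions, earlier
        assert hours_to_half(fast) < hours_to_half(slow)


class TestFitRateResponse:
    def test_noise_free_inversion(self):
        fit = fit_rate_response(exact_points(4.0, 5000.0), ci_method="none")
        assert fit.apparent_tb_c == pytest.approx(4.0, abs=1e-9)
        assert fit.thermal_time_ch == pytest.approx(5000.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle_with_noise(self):
        rng = np.random.default_rng(42)
        y = 0.0002 * TEMPS - 0.0008 + rng.normal(0, 5e-5, len(TEMPS))
        fit = fit_rate_response(
            [RatePoint(t, 1.0 / r) for t, r in zip(TEMPS, y)], ci_method="none"
        )
        m, b = ols_oracle(TEMPS, y)
        assert fit.m == pytest.approx(m, rel=1e-10)
        assert fit.b == pytest.approx(b, rel=1e-10)

    def test_two_points_rejected(self):
        with pytest.raises(InsufficientTemperaturesError):
            fit_rate_response(exact_points(4.0, 5000.0, temps=TEMPS[:2]))

    def test_negative_slope_marked_invalid(self):
        pts = [RatePoint(t, 1.0 / r) for t, r in zip(TEMPS, [5e-3, 4e-3, 3e-3, 2e-3, 1e-3])]
        fit = fit_rate_response(pts, ci_method="none")
        assert fit.status == "invalid_slope"
        assert not fit.valid
        assert np.isnan(fit.thermal_time_ch)

    def test_bootstrap_cis_cover_truth_and_are_seeded(self):
        rng = np.random.default_rng(1)
        rates = (TEMPS - 4.0) / 5000.0 + rng.normal(0, 2e-5, len(TEMPS))
        pts = [RatePoint(t, 1.0 / r) for t, r in zip(TEMPS, rates)]
        fit1 = fit_rate_response(pts, seed=9)
        fit2 = fit_rate_response(pts, seed=9)
        assert fit1.ci95_tb == fit2.ci95_tb  # deterministic given the seed
        lo, hi = fit1.ci95_tb
        assert lo < fit1.apparent_tb_c < hi
        lo, hi = fit1.ci95_theta
        assert lo < fit1.thermal_time_ch < hi

    def test_delta_method_agrees_with_bootstrap_roughly(self):
        rng = np.random.default_rng(3)
        rates = (TEMPS - 2.0) / 7000.0 + rng.normal(0, 2e-5, len(TEMPS))
        pts = [RatePoint(t, 1.0 / r) for t, r in zip(TEMPS, rates)]
        boot = fit_rate_response(pts, seed=0, n_boot=4000)
        x = TEMPS
        y = np.array([p.rate for p in pts])
        m, b = ols_oracle(x, y)
        resid = y - (m * x + b)
        sigma2 = float(resid @ resid) / (len(x) - 2)
        (d_lo, d_hi), _ = delta_method_cis(x, m, b, sigma2)
        b_lo, b_hi = boot.ci95_tb
        # same scale of uncertainty; delta uses a t critical value (df=3)
        # where the percentile bootstrap is effectively normal, so it is
        # wider by roughly t_{.975,3}/z_{.975} ~ 1.6
        ratio = (d_hi - d_lo) / (b_hi - b_lo)
        assert 1.1 < ratio < 2.3

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        tb=st.floats(min_value=-2.0, max_value=9.0),
        theta=st.floats(min_value=2000.0, max_value=12000.0),
    )
    def test_inversion_identity_property(self, tb, theta):
        fit = fit_rate_response(exact_points(tb, theta), ci_method="none")
        assert abs(fit.apparent_tb_c - tb) < 1e-8
        assert abs(fit.thermal_time_ch - theta) / theta < 1e-8


class TestEstimateAccession:
    def tc(self, temp, tb=4.0, theta=5000.0, complete=True, acc="A"):
        """Three-point course crossing (or plateauing below) 0.5."""
        t50 = theta / (temp - tb)
        if complete:
            return course([t50 - 24, t50, t50 + 24], [30, 50, 90], temp=temp, acc=acc)
        return course([t50 - 24, t50, t50 + 24], [20, 40, 40], temp=temp, acc=acc)

    def test_all_five_temperatures_fit(self):
        fit = estimate_accession([self.tc(t) for t in TEMPS], ci_method="none")
        assert isinstance(fit, ThermalTimeFit)
        assert fit.n_points == 5
        assert fit.apparent_tb_c == pytest.approx(4.0, abs=1e-8)

    def test_no_temperature_reaching_half_excluded(self):
        out = estimate_accession([self.tc(t, complete=False) for t in TEMPS])
        assert isinstance(out, AccessionExclusion)
        assert out.n_reached == 0

    def test_two_temperatures_is_insufficient(self):
        courses = [self.tc(t, complete=(t > 17)) for t in TEMPS]
        out = estimate_accession(courses)
        assert isinstance(out, AccessionExclusion)
        assert "insufficient temperatures" in out.reason
        assert out.n_reached == 2

    def test_mixed_accessions_rejected(self):
        with pytest.raises(ValueError, match="mix"):
            estimate_accession([self.tc(15.9, acc="A"), self.tc(17.8, acc="B")])


class TestTbThetaCurve:
    def test_noise_free_recovery(self):
        theta = np.array([2500.0, 5000.0, 8000.0, 11000.0])
        curve = fit_tb_theta_curve(10.0 - np.log(theta), theta)
        assert curve.a == pytest.approx(10.0)
        assert curve.c == pytest.approx(-1.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_tb_theta_curve([1.0, 2.0], [3000.0, 5000.0])

    def test_non_positive_theta_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_tb_theta_curve([1.0, 2.0, 3.0], [3000.0, -1.0, 5000.0])


class TestCorrelate:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = correlate(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_orthogonal_by_construction(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = x**2  # even function of a symmetric x: exactly uncorrelated
        r, _ = correlate(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r, _ = correlate(x, y)
        oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(oracle, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
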