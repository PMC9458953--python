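"""Segmented Arrhenius fitting, breakpoint search and intersection."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lfcr.arrhenius import (ArrheniusModel, InsufficientDataError,
                            ParallelSegmentsError, RatePoint, fit_segment,
                            intersect_segments, predict_rate, segmented_fit)
from lfcr.constants import CELSIUS_OFFSET, R_GAS


def rate_law(temp_c, k_ref=0.144, ea=19_000.0, t_ref=303.15):
    t = temp_c + CELSIUS_OFFSET
    return k_ref * math.exp(-ea / R_GAS * (1.0 / t - 1.0 / t_ref))


def two_regime(temp_c, ea_warm=19_000.0, ea_cold=65_700.0, break_c=15.0):
    if temp_c >= break_c:
        return rate_law(temp_c, ea=ea_warm)
    anchor = rate_law(break_c, ea=ea_warm)
    return anchor * math.exp(-ea_cold / R_GAS *
                             (1.0 / (temp_c + CELSIUS_OFFSET) - 1.0 / (break_c + CELSIUS_OFFSET)))


def brute_force_split(points):
    """Independent minimum-RSS shared-boundary search via normal equations."""
    pts = sorted(points, key=lambda p: -p.temperature_c)
    x = np.array([1.0 / p.temperature_k for p in pts])
    y = np.log([p.rate for p in pts])

    def rss(xs, ys):
        design = np.column_stack([np.ones_like(xs), xs])
        beta, *_ = np.linalg.lstsq(design, ys, rcond=None)
        resid = ys - design @ beta
        return float(resid @ resid)

    best = None
    for b in range(1, len(pts) - 1):
        total = rss(x[:b + 1], y[:b + 1]) + rss(x[b:], y[b:])
        if best is None or total < best[0] - 1e-15:
            best = (total, b)
    return best


class TestFitSegment:
    def test_two_point_fit_is_exact(self):
        points = [RatePoint(30.0, rate_law(30.0)), RatePoint(15.0, rate_law(15.0))]
        seg = fit_segment(points)
        assert seg.ea == pytest.approx(19_000.0, rel=1e-9)
        assert seg.r_squared == pytest.approx(1.0)

    def test_flat_rates_give_zero_activation_energy(self):
        seg = fit_segment([RatePoint(t, 0.1) for t in (30.0, 20.0, 10.0)])
        assert seg.slope == pytest.approx(0.0, abs=1e-9)
        assert seg.ea == pytest.approx(0.0, abs=1e-5)

    def test_noiseless_recovery_and_perfect_r2(self):
        points = [RatePoint(t, rate_law(t, ea=50_400.0)) for t in (30, 25, 20, 15)]
        seg = fit_segment(points)
        assert seg.ea == pytest.approx(50_400.0, rel=1e-9)
        assert seg.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_rates_excluded_with_warning(self):
        points = [RatePoint(30.0, 0.144), RatePoint(20.0, 0.1), RatePoint(10.0, 0.0)]
        with pytest.warns(UserWarning):
            seg = fit_segment(points)
        assert seg.n_points == 2

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_segment([RatePoint(30.0, 0.1), RatePoint(20.0, 0.0)])

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_ea_invariant_under_rate_rescaling(self, scale):
        base = [RatePoint(t, rate_law(t)) for t in (30, 25, 20, 15)]
        scaled = [RatePoint(p.temperature_c, p.rate * scale) for p in base]
        assert fit_segment(scaled).ea == pytest.approx(fit_segment(base).ea, rel=1e-6)

    def test_median_recovery_under_multiplicative_noise(self):
        # 5% lognormal noise, 200 replicates: the median fitted Ea stays
        # within 5% of the generating 50 kJ/mol
        rng = np.random.default_rng(1234)
        temps = (30.0, 25.0, 20.0, 15.0, 10.0)
        truth = 50_000.0
        fitted = []
        for _ in range(200):
            pts = [RatePoint(t, rate_law(t, ea=truth) * rng.lognormal(0.0, 0.05))
                   for t in temps]
            fitted.append(fit_segment(pts).ea)
        assert abs(np.median(fitted) - truth) / truth < 0.05


class TestSegmentedFit:
    def test_auto_recovers_generating_breakpoint(self):
        points = [RatePoint(t, two_regime(t)) for t in (30, 25, 20, 15, 12, 10)]
        model = segmented_fit(points, mode="auto")
        assert model.mode == "auto_split"
        assert model.warm.t_min_c == 15.0       # boundary point shared
        assert model.cold.t_max_c == 15.0
        assert model.warm.ea == pytest.approx(19_000.0, rel=1e-6)
        assert model.cold.ea == pytest.approx(65_700.0, rel=1e-6)
        assert model.t_crit_k == pytest.approx(288.15, abs=0.1)

    def test_single_regime_data_degenerates_gracefully(self):
        points = [RatePoint(t, rate_law(t)) for t in (30, 25, 20, 15, 10)]
        model = segmented_fit(points, mode="auto")
        assert model.cold.ea == pytest.approx(model.warm.ea, rel=1e-6)
        assert model.t_crit_k is None  # parallel segments have no crossing

    def test_fixed_split_shares_boundary_point(self):
        points = [RatePoint(t, two_regime(t)) for t in (30, 25, 20, 15, 10)]
        model = segmented_fit(points, mode="fixed", fixed_boundary_c=15.0)
        assert model.warm.n_points == 4
        assert model.cold.n_points == 2
        assert model.t_crit_k == pytest.approx(288.15, abs=1e-6)

    def test_fixed_split_requires_observed_boundary(self):
        points = [RatePoint(t, two_regime(t)) for t in (30, 25, 20, 15, 10)]
        with pytest.raises(InsufficientDataError):
            segmented_fit(points, mode="fixed", fixed_boundary_c=17.0)

    @pytest.mark.parametrize("n_points", [4, 5, 6, 7, 8])
    def test_auto_equals_enumeration_oracle(self, n_points):
        rng = np.random.default_rng(n_points * 101)
        for _ in range(10):
            temps = np.sort(rng.uniform(5.0, 35.0, size=n_points))[::-1]
            rates = np.exp(rng.normal(-2.0, 0.6, size=n_points))
            points = [RatePoint(t, r) for t, r in zip(temps, rates)]
            oracle_rss, oracle_b = brute_force_split(points)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = segmented_fit(points, mode="auto")
            # boundary index b means warm segment holds points[0..b]
            assert model.warm.n_points == oracle_b + 1


class TestIntersection:
    @staticmethod
    def _segments():
        warm = fit_segment([RatePoint(30.0, rate_law(30.0)),
                            RatePoint(20.0, rate_law(20.0))])
        cold = fit_segment([RatePoint(15.0, two_regime(15.0)),
                            RatePoint(10.0, two_regime(10.0))])
        return warm, cold

    def test_constructed_crossing_at_fifteen_degrees(self):
        warm, cold = self._segments()
        assert intersect_segments(warm, cold) == pytest.approx(288.15, abs=1e-6)

    def test_symmetric_in_argument_order(self):
        warm, cold = self._segments()
        assert intersect_segments(warm, cold) == pytest.approx(
            intersect_segments(cold, warm), rel=1e-12)

    def test_parallel_segments_rejected(self):
        warm, _ = self._segments()
        with pytest.raises(ParallelSegmentsError):
            intersect_segments(warm, warm)


class TestPrediction:
    def test_reproduces_fitted_points(self):
        seg = fit_segment([RatePoint(30.0, 0.144), RatePoint(15.0, 0.0973)])
        assert seg.predict(30.0) == pytest.approx(0.144, rel=1e-9)
        assert seg.predict(15.0) == pytest.approx(0.0973, rel=1e-9)

    def test_cold_segment_predicts_printed_low_temperature_rate(self):
        # cold segment anchored at the 15 degC crossing with Ea = 65.7 kJ/mol
        warm, cold = TestIntersection._segments()
        model = ArrheniusModel(warm=warm, cold=cold,
                               t_crit_k=intersect_segments(warm, cold), mode="fixed_split")
        assert predict_rate(model, 10.0) == pytest.approx(0.0599, abs=1e-4)

    def test_continuous_at_critical_temperature(self):
        # both segments agree at their crossing, so the piecewise
        # prediction is continuous there
        warm, cold = TestIntersection._segments()
        t_c = intersect_segments(warm, cold) - CELSIUS_OFFSET
        assert warm.predict(t_c) == pytest.approx(cold.predict(t_c), rel=1e-9)
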