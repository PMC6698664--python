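"""Growth-curve analysis: rates, lag detection, recovery classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oxkinetics as ox
from oxkinetics.exceptions import InconclusiveGrowthError, ValidationError
from oracles import exponential_rate_closed_form


class TestDoublingTime:
    def test_doubling_43_min_gives_published_growth_rate(self):
        assert ox.rate_from_doubling(43.0) == pytest.approx(0.967, abs=0.001)
        assert ox.rate_from_doubling(43.0) == pytest.approx(0.96, abs=0.01)

    def test_cm_treated_rate_is_one_fourth(self):
        ratio = ox.rate_from_doubling(170.0) / ox.rate_from_doubling(43.0)
        assert ratio == pytest.approx(43.0 / 170.0)
        assert ratio == pytest.approx(0.25, abs=0.003)

    @given(st.floats(1.0, 1000.0))
    @settings(max_examples=50, deadline=None)
    def test_exact_inverse_round_trip(self, td):
        assert ox.doubling_time(ox.rate_from_doubling(td)) == pytest.approx(td, rel=1e-12)

    def test_rejects_nonpositive(self):
        for fn in (ox.doubling_time, ox.rate_from_doubling):
            with pytest.raises(ValidationError):
                fn(0.0)


class TestFitExponential:
    def test_exact_exponential_recovered(self):
        t = np.arange(0, 121, 2.0)
        curve = ox.GrowthCurve(t, 0.02 * np.exp(0.94 * t / 60.0))
        assert ox.fit_exponential(curve, 0, 120) == pytest.approx(0.94, rel=1e-9)

    def test_doubling_every_43_min_closed_form(self):
        t = np.arange(0, 173, 4.0)
        curve = ox.GrowthCurve(t, 0.02 * 2 ** (t / 43.0))
        rate = ox.fit_exponential(curve, 0, 172)
        assert rate == pytest.approx(exponential_rate_closed_form(1.0, 2.0, 43.0), rel=1e-9)
        assert rate == pytest.approx(0.967, abs=0.001)

    def test_flat_curve_rate_zero(self):
        curve = ox.GrowthCurve(np.arange(0, 60, 2.0), np.full(30, 0.2))
        assert ox.fit_exponential(curve, 0, 58) == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        curve = ox.GrowthCurve(np.arange(0, 60, 2.0), np.full(30, 0.2))
        with pytest.raises(ValidationError):
            ox.fit_exponential(curve, 0, 5)


class TestInstantaneousRate:
    def test_constant_for_pure_exponential(self):
        t = np.arange(0, 200, 2.0)
        curve = ox.GrowthCurve(t, 0.02 * np.exp(0.96 * t / 60.0))
        rates = ox.instantaneous_growth_rate(curve)
        assert rates.shape == t.shape
        np.testing.assert_allclose(rates, 0.96, atol=1e-9)

    def test_arrested_segment_rate_near_zero(self):
        curve = ox.simulate_growth(0.96, od0=0.05, lag_min=60.0, lambda_post=0.94)
        rates = ox.instantaneous_growth_rate(curve)
        ts = curve.stress_time_min
        mid_lag = (curve.times_min > ts + 10) & (curve.times_min < ts + 50)
        np.testing.assert_allclose(rates[mid_lag], 0.0, atol=1e-9)

    def test_recovering_curve_crosses_half_rate_once_down_once_up(self):
        curve = ox.simulate_growth(0.96, od0=0.05, lag_min=38.0, lambda_post=0.94)
        rates = ox.instantaneous_growth_rate(curve)
        above = rates > 0.5 * 0.96
        flips = np.diff(above.astype(int))
        assert (flips == -1).sum() == 1 and (flips == 1).sum() == 1


class TestSimulateGrowth:
    def test_noiseless_piecewise_structure(self):
        curve = ox.simulate_growth(0.96, od0=0.05, od_stress=0.2, lag_min=38.0)
        ts = curve.stress_time_min
        pre = curve.times_min <= ts
        np.testing.assert_allclose(
            curve.od600[pre], 0.05 * np.exp(0.96 * curve.times_min[pre] / 60.0), rtol=1e-12
        )
        in_lag = (curve.times_min > ts) & (curve.times_min <= ts + 38.0)
        np.testing.assert_allclose(curve.od600[in_lag], 0.2, rtol=1e-12)

    def test_rejects_stress_od_below_start(self):
        with pytest.raises(ValidationError):
            ox.simulate_growth(0.96, od0=0.3, od_stress=0.2)

    def test_seeded_noise_reproducible(self):
        a = ox.simulate_growth(0.96, od0=0.05, noise_cv=0.02, seed=4)
        b = ox.simulate_growth(0.96, od0=0.05, noise_cv=0.02, seed=4)
        np.testing.assert_array_equal(a.od600, b.od600)


class TestDetectPhases:
    def test_recovers_published_parameters(self):
        """1.5 mM-like preset: 0.96/h before, 38-min lag, 0.94/h after."""
        curve = ox.simulate_growth(0.96, od0=0.05, od_stress=0.2, lag_min=38.0,
                                   lambda_post=0.94)
        ph = ox.detect_phases(curve)
        assert ph.recovered and not ph.declining
        assert ph.lambda_pre == pytest.approx(0.96, rel=0.02)
        assert ph.lambda_post == pytest.approx(0.94, rel=0.02)
        assert ph.lag_min == pytest.approx(38.0, abs=curve.sampling_min)

    def test_no_stress_exponential_has_zero_lag(self):
        t = np.arange(0, 200, 2.0)
        curve = ox.GrowthCurve(t, 0.05 * np.exp(0.96 * t / 60.0), stress_time_min=100.0)
        ph = ox.detect_phases(curve)
        assert ph.recovered and ph.lag_min == pytest.approx(0.0, abs=curve.sampling_min)

    @pytest.mark.parametrize("lag", [5.0, 15.0, 38.0, 90.0])
    def test_lag_sweep_recovered_within_one_sampling_interval(self, lag):
        curve = ox.simulate_growth(0.96, od0=0.05, lag_min=lag, lambda_post=0.94)
        ph = ox.detect_phases(curve)
        assert ph.lag_min == pytest.approx(lag, abs=curve.sampling_min)

    def test_detected_lag_monotone_in_true_lag_under_noise(self):
        detected = []
        for lag in (5.0, 15.0, 38.0, 90.0):
            curve = ox.simulate_growth(
                0.96, od0=0.05, lag_min=lag, lambda_post=0.94, noise_cv=0.02, seed=21
            )
            detected.append(ox.detect_phases(curve).lag_min)
        assert detected == sorted(detected)

    def test_plateau_then_decline_never_recovers_and_has_no_lag(self):
        curve = ox.simulate_growth(0.96, od0=0.05, mode="plateau_then_decline")
        ph = ox.detect_phases(curve)
        assert not ph.recovered and ph.declining
        assert ph.lag_min is None and ph.lambda_post is None

    def test_immediate_decline_flagged(self):
        curve = ox.simulate_growth(0.96, od0=0.05, mode="immediate_decline")
        ph = ox.detect_phases(curve)
        assert not ph.recovered and ph.declining

    def test_truncated_curve_is_inconclusive_not_a_nonrecovery_call(self):
        curve = ox.simulate_growth(0.96, od0=0.05, lag_min=38.0)
        ts = curve.stress_time_min
        keep = curve.times_min <= ts + 6
        short = ox.GrowthCurve(
            curve.times_min[keep], curve.od600[keep], stress_time_min=ts
        )
        with pytest.raises(InconclusiveGrowthError):
            ox.detect_phases(short)

    def test_summary_reports_phases(self):
        curve = ox.simulate_growth(0.96, od0=0.05, lag_min=38.0)
        text = ox.detect_phases(curve).summary()
        assert "lambda_pre" in text and "recovered" in text
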