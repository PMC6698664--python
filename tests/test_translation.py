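"""Elongation-rate inference: closed forms, Schleif fits, stalled calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oxkinetics as ox
from oxkinetics import translation as tr
from oxkinetics.exceptions import FitFailureError, ValidationError
from oracles import grid_search_t_first


class TestElongationRate:
    @pytest.mark.parametrize(
        "length, t_first, expected",
        [
            (1024, 350.0, pytest.approx(3.01, abs=0.01)),  # ~3 aa/s at 5 min post-shock
            (1024, 1200.0, pytest.approx(0.86, abs=0.01)),  # ~1 aa/s at the high dose
            (100, 110.0, pytest.approx(1.0)),
        ],
    )
    def test_worked_examples(self, length, t_first, expected):
        assert ox.elongation_rate(length, t_first) == expected

    def test_rejects_t_first_at_or_below_initiation(self):
        with pytest.raises(ValidationError):
            ox.elongation_rate(1024, 10.0)
        with pytest.raises(ValidationError):
            ox.elongation_rate(1024, 3.0)

    @given(
        t1=st.floats(20, 5000),
        t2=st.floats(20, 5000),
        length=st.integers(50, 2000),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_t_first_linear_in_length(self, t1, t2, length):
        if t1 == t2:
            return
        lo, hi = sorted((t1, t2))
        assert ox.elongation_rate(length, lo) > ox.elongation_rate(length, hi)
        # linear in length at fixed time
        assert ox.elongation_rate(2 * length, t1) == pytest.approx(
            2 * ox.elongation_rate(length, t1)
        )


class TestTranslationTime:
    def test_katg_at_one_aa_per_s_takes_twelve_minutes(self):
        t = ox.translation_time(726, 1.0)
        assert t == 726.0
        assert t / 60.0 == pytest.approx(12.1, abs=0.1)

    def test_simple_division_and_stalled_sentinel(self):
        assert ox.translation_time(1024, 16.0) == 64.0
        assert math.isinf(ox.translation_time(726, 0.0))
        with pytest.raises(ValidationError):
            ox.translation_time(726, -1.0)


class TestSimulateInduction:
    def test_noiseless_signal_flat_until_t_first_then_quadratic(self):
        rep = ox.ReporterSpec("x", 1024)
        trace = ox.simulate_induction(rep, er=16.0, times_s=np.arange(0, 601, 10.0))
        t_first = 10 + 1024 / 16.0  # 74 s
        flat = trace.times_s <= t_first
        assert np.all(trace.signal[flat] == 0.0)
        assert np.all(trace.signal[~flat] > 0.0)
        # exactly quadratic beyond T_first
        rise = trace.times_s > t_first
        expected = 1e-3 * (trace.times_s[rise] - t_first) ** 2
        np.testing.assert_allclose(trace.signal[rise], expected, rtol=1e-12)

    def test_slow_rate_rises_only_after_350_s(self):
        trace = ox.simulate_induction(ox.LACZ, er=3.01, times_s=np.arange(0, 961, 30.0))
        assert np.all(trace.signal[trace.times_s <= 350] == 0.0)
        assert trace.signal[trace.times_s > 360][0] > 0.0

    def test_seeded_reproducibility_bit_identical(self):
        kw = dict(times_s=np.arange(0, 601, 10.0), noise_sd=5.0, seed=99)
        a = ox.simulate_induction(ox.LACZ, 16.0, **kw)
        b = ox.simulate_induction(ox.LACZ, 16.0, **kw)
        np.testing.assert_array_equal(a.signal, b.signal)

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(ValidationError):
            ox.simulate_induction(ox.LACZ, er=0.0)


class TestSimulateStalled:
    def test_flat_at_baseline_and_zero_case(self):
        trace = ox.simulate_stalled(ox.LACZ, baseline=0.0)
        assert np.all(trace.signal == 0.0)
        assert trace.span_s >= 2400.0

    def test_two_seeds_differ_but_share_flat_expectation(self):
        a = ox.simulate_stalled(ox.LACZ, noise_sd=1.0, seed=1)
        b = ox.simulate_stalled(ox.LACZ, noise_sd=1.0, seed=2)
        assert not np.array_equal(a.signal, b.signal)
        assert abs(a.signal.mean()) < 1.0 and abs(b.signal.mean()) < 1.0

    def test_rejects_short_grid(self):
        with pytest.raises(ValidationError):
            ox.simulate_stalled(ox.LACZ, times_s=np.arange(0, 1200, 30.0))


class TestSchleifFit:
    def test_noiseless_exact_recovery_at_350_s(self):
        trace = ox.simulate_induction(ox.LACZ, er=3.01, times_s=np.arange(0, 961, 30.0))
        fit = ox.schleif_fit(trace)
        assert not fit.stalled
        assert fit.t_first_s == pytest.approx(350.2, abs=30.0)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.er_aa_per_s == pytest.approx(3.01, rel=1e-6)

    @pytest.mark.parametrize("er", [0.8, 1.0, 3.0, 8.0, 16.0])
    @pytest.mark.parametrize("length", [639, 952, 1024])
    def test_noiseless_round_trip_over_grid(self, er, length):
        rep = ox.ReporterSpec("rep", length)
        trace = ox.simulate_induction(rep, er=er)
        fit = ox.schleif_fit(trace)
        dt = float(np.diff(trace.times_s).min())
        t_first_true = 10 + length / er
        assert abs(fit.t_first_s - t_first_true) <= dt
        assert fit.er_aa_per_s == pytest.approx(er, rel=0.05)

    @pytest.mark.parametrize("er", [0.8, 1.0, 3.0, 8.0, 16.0])
    def test_noiseless_agrees_with_raw_signal_grid_search_oracle(self, er):
        trace = ox.simulate_induction(ox.LACZ, er=er)
        fit = ox.schleif_fit(trace)
        t_oracle = grid_search_t_first(trace.times_s, trace.signal)
        er_oracle = ox.elongation_rate(1024, t_oracle)
        assert fit.er_aa_per_s == pytest.approx(er_oracle, rel=0.03)

    def test_noisy_ensemble_mean_within_5pct_and_tracks_oracle(self):
        """100 traces at 5% amplitude noise, ER=8, L=1024: the ensemble mean
        recovers the true rate within 5%, and the sqrt-plot estimate stays in
        line with the raw-signal grid-search oracle."""
        er, n = 8.0, 100
        grid = tr.default_sampling_grid(er)
        t_first = 10 + 1024 / er
        span = 1e-3 * (grid[-1] - t_first) ** 2
        fits, oracle = [], []
        for seed in range(n):
            trace = ox.simulate_induction(
                ox.LACZ, er, amplitude=1e-3, times_s=grid,
                noise_sd=0.05 * span, seed=seed,
            )
            fits.append(ox.schleif_fit(trace).er_aa_per_s)
            if seed < 25:  # oracle is slow; a subsample suffices for tracking
                oracle.append(
                    ox.elongation_rate(1024, grid_search_t_first(trace.times_s, trace.signal))
                )
        assert np.mean(fits) == pytest.approx(er, rel=0.05)
        assert np.mean(oracle) == pytest.approx(np.mean(fits[:25]), rel=0.1)

    def test_flat_40min_trace_is_stalled_with_zero_rate(self):
        fit = ox.schleif_fit(ox.simulate_stalled(ox.LACZ))
        assert fit.stalled and fit.er_aa_per_s == 0.0
        assert math.isnan(fit.t_first_s)

    def test_noisy_flat_trace_is_stalled(self):
        fit = ox.schleif_fit(ox.simulate_stalled(ox.LACZ, noise_sd=18.0, seed=5))
        assert fit.stalled and fit.er_aa_per_s == 0.0

    def test_stalled_classification_monotone_under_truncation(self):
        trace = ox.simulate_stalled(ox.LACZ, noise_sd=10.0, seed=7)
        assert ox.schleif_fit(trace).stalled
        # truncating an already-stalled trace never resurrects a rate
        for n in (len(trace) - 5, len(trace) - 15):
            sub = ox.InductionTrace(
                trace.times_s[:n], trace.signal[:n], trace.reporter
            )
            # shorter horizon: evaluate within the truncated span
            fit = ox.schleif_fit(sub, max_horizon_s=sub.span_s)
            assert fit.stalled

    def test_decreasing_trace_raises_fit_failure_not_stalled(self):
        t = np.arange(0, 601, 10.0)
        sig = 500.0 - 0.5 * t  # clearly above 'baseline' yet falling
        sig[:4] = 0.0
        with pytest.raises(FitFailureError):
            ox.schleif_fit(ox.InductionTrace(t, sig, ox.LACZ))

    def test_rejects_trace_shorter_than_baseline_window(self):
        with pytest.raises(ValidationError):
            ox.InductionTrace(np.arange(4.0), np.zeros(4), ox.LACZ)

    def test_sqrt_of_noiseless_rise_exactly_linear(self):
        trace = ox.simulate_induction(ox.LACZ, er=8.0)
        t_first = 10 + 1024 / 8.0
        rise = trace.times_s > t_first
        y = np.sqrt(trace.signal[rise])
        r = np.corrcoef(trace.times_s[rise], y)[0, 1]
        assert r**2 > 1 - 1e-10

    def test_summary_mentions_rate_and_stalled_status(self):
        fit = ox.schleif_fit(ox.simulate_induction(ox.LACZ, er=16.0))
        text = fit.summary()
        assert "ER [aa/s]" in text and "stalled" in text
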