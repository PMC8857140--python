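"""Oscillation metrics: onset detection, magnitude, periods, sensitivity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biofilmosc.metrics import (AnalysisError, OnsetEvent, detect_onsets,
                                onset_experiment, oscillation_magnitude,
                                period_by_size, sensitivity)
from biofilmosc.model1d import OscillationTrace


def _trace(t, v, width=0.3):
    n = len(t)
    z = np.zeros(n)
    w = np.full(n, width) if np.isscalar(width) else np.asarray(width)
    return OscillationTrace(time_h=np.asarray(t, float), width_mm=w,
                            dLdt_mm_per_h=z, mean_V_mV=np.asarray(v, float),
                            mean_K_mM=z, mean_Gin_mM=z, mean_Kin_mM=z,
                            mean_T=z, mean_A=z)


def _brute_force_minima(t, v, width, eps=0.5, guard=0.5):
    """Independent O(N) scan: strict local minima with the same debounce."""
    out = []
    for i in range(1, len(v) - 1):
        if not v[i] < v[i - 1]:
            continue
        j = i + 1
        while j < len(v) and v[j] == v[i]:
            j += 1
        if j >= len(v) or v[j] <= v[i]:
            continue
        pre = [v[k] for k in range(len(t)) if t[i] - guard <= t[k] <= t[i]]
        post = [v[k] for k in range(len(t)) if t[i] <= t[k] <= t[i] + guard]
        if max(pre) - v[i] < eps or max(post) - v[i] < eps:
            continue
        out.append(i)
    return out


class TestDetectOnsets:
    def test_monotone_series_has_no_events(self):
        t = np.arange(0, 10, 0.01)
        assert detect_onsets(_trace(t, -150 - t)) == []

    def test_cosine_minima_at_expected_times(self):
        t = np.arange(0, 12, 0.01)
        v = 10 * np.cos(2 * np.pi * t / 4.0) - 160
        ev = detect_onsets(_trace(t, v, width=0.3))
        assert [pytest.approx(e.time_h, abs=0.011) for e in ev] == [2, 6, 10]
        assert all(e.sustained for e in ev)

    def test_small_biofilm_events_flagged_unsustained(self):
        t = np.arange(0, 12, 0.01)
        v = 10 * np.cos(2 * np.pi * t / 4.0) - 160
        ev = detect_onsets(_trace(t, v, width=0.1))   # doubled width 200 µm
        assert ev and not any(e.sustained for e in ev)

    def test_shallow_wiggles_are_debounced(self):
        t = np.arange(0, 10, 0.01)
        v = -150 + 0.1 * np.sin(2 * np.pi * t)        # 0.2 mV peak-to-peak
        assert detect_onsets(_trace(t, v)) == []

    def test_too_short_trace_raises(self):
        with pytest.raises(AnalysisError):
            detect_onsets(_trace([0.0, 1.0], [-150.0, -151.0]))

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-200.0, -100.0), min_size=20, max_size=60))
    def test_agrees_with_brute_force_scan(self, vals):
        t = np.arange(len(vals)) * 0.25
        tr = _trace(t, vals, width=0.3)
        got = [e.time_h for e in detect_onsets(tr)]
        want = [t[i] for i in _brute_force_minima(t, vals, 0.3)]
        assert got == want


class TestMagnitude:
    def test_constant_series_is_zero(self):
        assert oscillation_magnitude(np.full(10, 5.0)) == 0.0

    def test_direct_max_minus_min(self):
        assert oscillation_magnitude(np.array([1.0, 3.0, 2.0, 0.5])) == 2.5

    def test_window_restriction(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        k = np.array([0.0, 10.0, 4.0, 6.0])
        assert oscillation_magnitude(k, t, window=(2.0, 3.0)) == 2.0

    def test_empty_window_raises(self):
        with pytest.raises(AnalysisError):
            oscillation_magnitude(np.array([1.0]), np.array([0.0]),
                                  window=(5.0, 6.0))


class TestPeriodBySize:
    def test_uniform_spacing(self):
        ev = [OnsetEvent(2.0, 350.0, True), OnsetEvent(6.0, 400.0, True),
              OnsetEvent(10.0, 450.0, True)]
        assert period_by_size(ev) == [(400.0, 4.0), (450.0, 4.0)]

    def test_single_event_gives_empty(self):
        assert period_by_size([OnsetEvent(2.0, 350.0, True)]) == []

    def test_unsustained_events_are_ignored(self):
        ev = [OnsetEvent(1.0, 200.0, False), OnsetEvent(5.0, 350.0, True),
              OnsetEvent(9.0, 380.0, True)]
        assert period_by_size(ev) == [(380.0, 4.0)]


class TestOnsetExperiment:
    def test_deterministic_under_fixed_seed(self, p):
        a = onset_experiment(p, n_reps=1, t_end=6.0, seed=7)
        b = onset_experiment(p, n_reps=1, t_end=6.0, seed=7)
        assert np.array_equal(a.onset_sizes_um, b.onset_sizes_um)
        assert a.censored == b.censored

    def test_zero_jitter_makes_replicates_identical(self, p):
        r = onset_experiment(p, n_reps=3, base_width_um=150.0,
                             jitter_um=0.0, t_end=6.0, seed=3)
        assert len(r.onset_sizes_um) == 3 and r.censored == 0
        assert np.ptp(r.onset_sizes_um) == 0.0
        assert np.ptp(r.initial_widths_um) == 0.0

    def test_short_horizon_censors_instead_of_dropping_silently(self, p):
        r = onset_experiment(p, n_reps=2, t_end=0.5, seed=0)
        assert r.censored + len(r.onset_sizes_um) == 2
        assert r.censored == 2   # nothing sustains within half an hour


class TestSensitivityProtocol:
    def test_quadratic_objective_gives_twenty_percent(self, p):
        """O(p) = p² at p = 2: dO/dp = 4 (h→0) and the percent formula
        yields dO/dp·0.1·|p|/O·100 = 20%."""
        from biofilmosc.params import denormalize_units
        p2 = p.with_overrides(delta_K=2.0)

        def obj(params):
            return denormalize_units(params).delta_K ** 2

        r = sensitivity(p2, "delta_K", h=1e-6, objective=obj)
        assert r.derivative == pytest.approx(4.0, rel=1e-4)
        assert r.percent_per_10pct == pytest.approx(20.0, rel=1e-4)

    def test_memoized_baseline_matches_fresh_computation(self, p):
        def obj(params):
            from biofilmosc.params import denormalize_units
            return 3.0 * abs(denormalize_units(params).V_th)

        a = sensitivity(p, "V_th", objective=obj)
        b = sensitivity(p, "V_th", objective=obj,
                        baseline_O=obj(p))
        assert a.percent_per_10pct == b.percent_per_10pct

    def test_reporter_parameters_are_rejected(self, p):
        with pytest.raises(AnalysisError):
            sensitivity(p, "alpha_T")

    def test_zero_baseline_reports_undefined_percent(self, p):
        with pytest.raises(AnalysisError):
            sensitivity(p, "V_th", objective=lambda q: 0.0)
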