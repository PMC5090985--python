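"""Scan line, event detection, cubic-peak fitting and per-scan summaries."""

import numpy as np
import pytest

from xlf.breath_analysis import (
    BreathEvent,
    DegenerateTraceError,
    NoBreathsError,
    SamplingRateError,
    UnfittableEventError,
    analyze_trace,
    bandpass_trace,
    detect_breaths,
    fit_breath,
    scan_line_level,
    slope_metrics,
    summarize_scan,
)
from xlf.movie_io import TraceRecord
from xlf.synthetic import TraceSimConfig, simulate_trace
from xlf.xtf_extract import XTFTrace


def _trace(values, dt_ms=33.0):
    values = np.asarray(values, float)
    return XTFTrace(time_ms=np.arange(values.size) * dt_ms, value=values)


class TestScanLine:
    def test_definition_mean_plus_033_sd(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 500)
        v = (v - v.mean()) / v.std(ddof=1)  # mean 0, sample SD 1
        assert scan_line_level(_trace(v)) == pytest.approx(0.33, abs=1e-12)

    def test_hand_computed_example(self):
        # values [0,1,0,1]: mean 0.5, sample SD 0.57735 -> 0.69053
        assert scan_line_level(_trace([0, 1, 0, 1])) == pytest.approx(0.69053, abs=1e-5)

    def test_constant_trace_rejected(self):
        with pytest.raises(DegenerateTraceError):
            scan_line_level(_trace([1.0] * 10))


class TestDetection:
    def test_all_below_level_gives_no_events(self):
        assert detect_breaths(_trace(np.zeros(50)), level=1.0) == []

    def test_single_triangular_pulse(self):
        v = np.zeros(41)
        v[15:26] = 1.0 - np.abs(np.arange(-5, 6)) / 6.0
        events = detect_breaths(_trace(v), level=0.1)
        assert len(events) == 1
        assert events[0].start_ms < 20 * 33.0 < events[0].end_ms

    def test_boundary_touching_runs_discarded(self):
        v = np.ones(30)  # entirely above level, touches both ends
        assert detect_breaths(_trace(v), level=0.5) == []

    def test_short_runs_discarded(self):
        v = np.zeros(30)
        v[10:14] = 1.0  # 4 interior samples < 5
        assert detect_breaths(_trace(v), level=0.5) == []

    def test_matches_brute_force_oracle_on_random_traces(self):
        """Detection equals a per-sample brute-force run finder."""
        rng = np.random.default_rng(123)
        for _ in range(60):
            n = int(rng.integers(20, 1000))
            v = rng.normal(0, 1, n)
            level = float(rng.normal(0, 0.5))
            events = detect_breaths(_trace(v), level)
            oracle = brute_force_events(v, level)
            assert [(e_i, e_j) for e_i, e_j in oracle] == [
                (int(np.searchsorted(np.arange(n) * 33.0, e.sample_times_ms[1], side="left")),
                 int(np.searchsorted(np.arange(n) * 33.0, e.sample_times_ms[-2], side="left")))
                for e in events
            ]

    def test_simulator_ground_truth_event_count(self):
        trace, truth = simulate_trace(TraceSimConfig(noise_sd=0.0))
        events = detect_breaths(trace, scan_line_level(trace))
        assert len(events) == truth.n_events
        for event, g in zip(events, truth.events):
            assert event.start_ms < g.peak_time_ms < event.end_ms


def brute_force_events(values, level):
    """Independent oracle: scan every sample, mark maximal runs above level,
    apply the completeness and minimum-length rules."""
    runs = []
    in_run = False
    for i, v in enumerate(values):
        if v > level and not in_run:
            start, in_run = i, True
        elif v <= level and in_run:
            runs.append((start, i - 1))
            in_run = False
    if in_run:
        runs.append((start, len(values) - 1))
    return [
        (i, j)
        for i, j in runs
        if i > 0 and j < len(values) - 1 and (j - i + 1) >= 5
    ]


def _event_from_reversed_x(x, values, level, dur_ms=1000.0):
    """Build a BreathEvent whose interior samples sit at reversed normalized
    positions ``x`` with the given values."""
    t = dur_ms - np.asarray(x, float) * dur_ms
    order = np.argsort(t)
    return BreathEvent(
        start_ms=0.0,
        end_ms=dur_ms,
        sample_times_ms=np.concatenate(([0.0], t[order], [dur_ms])),
        sample_values=np.concatenate(([level], np.asarray(values, float)[order], [level])),
        level=level,
    )


class TestFit:
    def test_symmetric_parabola(self):
        """y = 1 - 4(x-0.5)^2 gives b1 = 0.5, t_in = 50%, b3 = 4, b5 = 1 and
        vanishing odd terms."""
        x = np.linspace(0.1, 0.9, 33)
        v = 1.0 - 4.0 * (x - 0.5) ** 2
        p = fit_breath(_event_from_reversed_x(x, v, level=v.min() - 0.1))
        assert p.b1 == pytest.approx(0.5, abs=1e-9)
        assert p.t_in_pct == pytest.approx(50.0, abs=1e-7)
        assert p.b3 == pytest.approx(4.0, abs=1e-9)
        assert p.b5 == pytest.approx(1.0, abs=1e-9)
        assert abs(p.b2) < 1e-9 and abs(p.b4) < 1e-9

    def test_exact_recovery_from_model(self):
        """41 samples drawn exactly from the shifted cubic with
        (b1, b2, b3, b4, b5) = (0.40, 2.0, 8.0, 0, 1.0) and the peak on a
        sample are recovered to 1e-9."""
        b1, b2, b3, b5 = 0.40, 2.0, 8.0, 1.0
        x = np.linspace(0.0, 1.0, 41)[1:-1]  # 0.40 = 16/40 is a sample point
        u = x - b1
        v = b2 * u**3 - b3 * u**2 + b5
        p = fit_breath(_event_from_reversed_x(x, v, level=v.min() - 0.5))
        assert p.b1 == pytest.approx(b1, abs=1e-9)
        assert p.b2 == pytest.approx(b2, abs=1e-9)
        assert p.b3 == pytest.approx(b3, abs=1e-9)
        assert abs(p.b4) < 1e-9
        assert p.b5 == pytest.approx(b5, abs=1e-9)

    def test_flat_event_unfittable(self):
        x = np.linspace(0.1, 0.9, 11)
        with pytest.raises(UnfittableEventError):
            fit_breath(_event_from_reversed_x(x, np.full(11, 2.0), level=1.0))

    def test_peak_position_invariants(self):
        """For every fitted simulated event: 0 < b1 < 1, 0 < t_in < 100 and
        the sample argmax lies inside the event bounds."""
        trace, _ = simulate_trace(TraceSimConfig(noise_sd=0.05, seed=9))
        level, events, params, _ = analyze_trace(trace)
        for event, p in zip(events, params):
            t_int = event.sample_times_ms[1:-1]
            t_max = t_int[int(np.argmax(event.sample_values[1:-1]))]
            assert event.start_ms < t_max <= event.end_ms
            assert 0.0 < p.b1 < 1.0
            assert 0.0 < p.t_in_pct < 100.0
            assert p.t_in_pct == pytest.approx(100.0 * (1.0 - p.b1), abs=1e-9)


class TestSummary:
    def test_three_identical_events_average_to_one(self):
        x = np.linspace(0.1, 0.9, 21)
        v = 1.0 - 4.0 * (x - 0.5) ** 2
        p = fit_breath(_event_from_reversed_x(x, v, level=v.min() - 0.1))
        trace, _ = simulate_trace(TraceSimConfig(noise_sd=0.0))
        s = summarize_scan([p, p, p], trace)
        assert s.n_events == 3
        assert s.mean_b3 == p.b3
        assert s.mean_t_in_pct == p.t_in_pct

    def test_bpm_from_protocol_duration(self):
        """24 events in a 34.13 s trace give 42.19 breaths per minute."""
        trace, truth = simulate_trace(TraceSimConfig(noise_sd=0.0))
        _, _, params, summary = analyze_trace(trace)
        assert summary.n_events == 24
        assert summary.bpm == pytest.approx(42.19, abs=0.01)

    def test_slope_metrics_on_ramp(self):
        t = np.arange(100) * 10.0  # ms
        v = 3.0 * (t / 1000.0)  # slope 3 per second
        assert slope_metrics(XTFTrace(time_ms=t, value=v)) == (
            pytest.approx(3.0), pytest.approx(3.0))

    def test_min_max_slope_bracket_zero_on_breathing_trace(self):
        trace, _ = simulate_trace(TraceSimConfig(noise_sd=0.0))
        _, _, _, s = analyze_trace(trace)
        assert s.min_slope < 0 < s.max_slope

    def test_no_events_raises(self):
        trace, _ = simulate_trace(TraceSimConfig(noise_sd=0.0))
        with pytest.raises(NoBreathsError):
            summarize_scan([], trace)


class TestBandpass:
    fs = 1000.0
    t = np.arange(30000) / 1000.0  # 30 s at 1 kHz

    def _record(self, values):
        return TraceRecord(time_ms=self.t * 1000.0, value=values)

    def test_constant_rejected_to_zero(self):
        out = bandpass_trace(self._record(np.full(self.t.size, 5.0)))
        assert np.abs(out.value).max() < 1e-9

    def test_passband_sinusoid_preserved(self):
        v = np.sin(2 * np.pi * 5.0 * self.t)
        out = bandpass_trace(self._record(v))
        mid = slice(10000, 20000)  # avoid edge transients of the 0.5 Hz edge
        assert np.abs(out.value[mid]).max() == pytest.approx(1.0, rel=0.02)

    def test_slow_drift_attenuated(self):
        v = np.sin(2 * np.pi * 0.05 * self.t)
        out = bandpass_trace(self._record(v))
        mid = slice(10000, 20000)
        assert np.abs(out.value[mid]).max() < 0.1

    def test_low_sampling_rate_rejected(self):
        rec = TraceRecord(time_ms=np.arange(100) * 40.0, value=np.zeros(100))  # 25 Hz
        with pytest.raises(SamplingRateError):
            bandpass_trace(rec)
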