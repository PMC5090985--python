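"""Simulator properties: determinism, ground-truth consistency, closure,
effect directions."""

import numpy as np
import pytest

from xlf.breath_analysis import analyze_trace, detect_breaths, scan_line_level
from xlf.synthetic import (
    CohortSimConfig,
    MethacholineSimConfig,
    StackSimConfig,
    TraceSimConfig,
    simulate_cohort,
    simulate_methacholine,
    simulate_stack,
    simulate_trace,
)
from xlf.xtf_extract import compute_xtf


class TestTraceSimulation:
    def test_protocol_event_count(self):
        """34.13 s at one event per 1400 ms holds 24 complete breaths."""
        _, truth = simulate_trace(TraceSimConfig(noise_sd=0.0))
        assert truth.n_events == 24

    def test_same_seed_bit_identical(self):
        t1, _ = simulate_trace(TraceSimConfig(seed=7))
        t2, _ = simulate_trace(TraceSimConfig(seed=7))
        np.testing.assert_array_equal(t1.value, t2.value)

    def test_different_seeds_differ(self):
        t1, _ = simulate_trace(TraceSimConfig(seed=7))
        t2, _ = simulate_trace(TraceSimConfig(seed=8))
        assert not np.array_equal(t1.value, t2.value)

    def test_ground_truth_boundaries_match_detected_runs(self, noiseless_scan):
        trace, truth = noiseless_scan
        events = detect_breaths(trace, scan_line_level(trace))
        assert len(events) == truth.n_events
        for e, g in zip(events, truth.events):
            assert e.start_ms == pytest.approx(g.start_ms, abs=1e-9)
            assert e.end_ms == pytest.approx(g.end_ms, abs=1e-9)

    def test_too_short_breath_period_rejected(self):
        with pytest.raises(ValueError, match="shorter than 5 samples"):
            simulate_trace(TraceSimConfig(breath_period_ms=200.0))

    def test_noiseless_closure_detect_fit(self, noiseless_scan):
        """Detect -> fit on noiseless data reproduces ground truth to 1e-6
        relative (b2, b3, b5) and b1 within one sample."""
        trace, truth = noiseless_scan
        _, _, params, _ = analyze_trace(trace)
        one_sample = trace.sample_interval_ms
        for p, g in zip(params, truth.events):
            assert p.b2 == pytest.approx(g.b2, rel=1e-6)
            assert p.b3 == pytest.approx(g.b3, rel=1e-6)
            assert p.b5 == pytest.approx(g.b5, rel=1e-6)
            assert abs(p.b1 - g.b1) * p.duration_ms <= one_sample
            assert g.b4 == 0.0

    def test_inspiration_fraction_monotonicity(self):
        """Lower simulated inspiration fraction -> lower measured t_in and
        higher measured b1."""
        t_ins, b1s = [], []
        for f in (0.30, 0.40, 0.50):
            trace, _ = simulate_trace(TraceSimConfig(noise_sd=0.0, inspiration_fraction=f))
            s = analyze_trace(trace)[3]
            t_ins.append(s.mean_t_in_pct)
            b1s.append(s.mean_b1)
        assert t_ins[0] < t_ins[1] < t_ins[2]
        assert b1s[0] > b1s[1] > b1s[2]


class TestStackSimulation:
    def test_zero_noise_unity_gain_closure(self):
        """XTF extracted from the stack equals the breathing signal to 1e-9."""
        stack, rois, _ = simulate_stack(StackSimConfig())
        xtf = compute_xtf(stack, rois)
        signal, _ = simulate_trace(TraceSimConfig(noise_sd=0.0))
        assert np.abs(xtf.value - signal.value).max() < 1e-9

    def test_constant_gain_invariance(self):
        cfg = StackSimConfig()
        stack, rois, _ = simulate_stack(cfg)
        stack2, _, _ = simulate_stack(StackSimConfig(b0=2 * cfg.b0))
        x1, x2 = compute_xtf(stack, rois), compute_xtf(stack2, rois)
        np.testing.assert_allclose(x1.value, x2.value, atol=1e-12)

    def test_pixel_noise_preserves_scan_mean_b5(self):
        """1% pixel noise leaves the per-scan mean b5 within 5% of truth."""
        ok = 0
        for seed in range(10):
            cfg = StackSimConfig(trace=TraceSimConfig(seed=seed), pixel_noise_sd=10.0)
            stack, rois, truth = simulate_stack(cfg)
            s = analyze_trace(compute_xtf(stack, rois))[3]
            ok += abs(s.mean_b5 - truth.mean("b5")) / truth.mean("b5") < 0.05
        assert ok >= 9

    def test_gain_drift_removed_by_detrend(self):
        """A 4% tube-gain drift changes the detrended scan summary by < 2%
        relative to a drift-free acquisition."""
        from xlf.xtf_extract import detrend_xtf

        drifted, rois, _ = simulate_stack(StackSimConfig(tube_gain_drift=0.04))
        steady, _, _ = simulate_stack(StackSimConfig())
        s_drift = analyze_trace(detrend_xtf(compute_xtf(drifted, rois)))[3]
        s_steady = analyze_trace(detrend_xtf(compute_xtf(steady, rois)))[3]
        assert s_drift.mean_b5 == pytest.approx(s_steady.mean_b5, rel=0.02)
        assert s_drift.mean_b3 == pytest.approx(s_steady.mean_b3, rel=0.02)


class TestCohortSimulation:
    def test_zero_variability_gives_identical_animals(self):
        cfg = CohortSimConfig(variability_sd=0.0, n_per_group=3,
                              base=TraceSimConfig(noise_sd=0.0))
        cohort = simulate_cohort(cfg)
        for animals in cohort.values():
            v0 = animals[0][0].value
            for trace, _ in animals[1:]:
                np.testing.assert_array_equal(trace.value, v0)

    def test_determinism(self):
        c1 = simulate_cohort(CohortSimConfig(seed=3))
        c2 = simulate_cohort(CohortSimConfig(seed=3))
        for g in c1:
            for (t1, _), (t2, _) in zip(c1[g], c2[g]):
                np.testing.assert_array_equal(t1.value, t2.value)

    def test_treated_group_intermediate(self):
        """SAA-DEX group means for b3 and t_in lie between CN and SAA."""
        cohort = simulate_cohort(CohortSimConfig(seed=1))
        means = {}
        for name, animals in cohort.items():
            sums = [analyze_trace(tr)[3] for tr, _ in animals]
            means[name] = (
                np.mean([s.mean_b3 for s in sums]),
                np.mean([s.mean_t_in_pct for s in sums]),
            )
        for k in (0, 1):
            assert means["SAA"][k] < means["SAA-DEX"][k] < means["CN"][k]

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            CohortSimConfig(n_per_group=1)


class TestMethacholineSimulation:
    def test_paired_structure_and_determinism(self):
        cfg = MethacholineSimConfig(seed=2, n_animals=3)
        r1, r2 = simulate_methacholine(cfg), simulate_methacholine(cfg)
        assert list(r1) == [0.0, 3.0, 10.0, 50.0]
        for d in r1:
            assert len(r1[d]) == 3
            for (t1, _), (t2, _) in zip(r1[d], r2[d]):
                np.testing.assert_array_equal(t1.value, t2.value)

    def test_steepness_declines_with_dose(self):
        res = simulate_methacholine(MethacholineSimConfig(seed=1))
        mean_b3 = [
            np.mean([g.mean("b3") for _, g in res[d]]) for d in (0.0, 3.0, 10.0, 50.0)
        ]
        assert mean_b3[0] > mean_b3[1] > mean_b3[2] > mean_b3[3]
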