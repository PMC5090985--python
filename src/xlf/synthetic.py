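"""Synthetic breathing traces, radiograph stacks and cohorts with ground truth.

The generator emulates the acquisition protocol -- 1024 frames at 30 frames/s
(34.13 s of chest movement) with the anesthesia-adjusted rate of roughly one
breathing event per 1400 ms -- so that every pipeline stage can be exercised
without animal data.

Each breath is a pulse drawn from the analysis model itself: a cubic with a
stationary maximum (the ``b4 = 0`` case), so that exact parameter recovery is
well defined.  A cubic has four degrees of freedom and they are spent on

* the pulse value at both window edges (``-edge_depth * amplitude``, the
  inter-breath baseline, continuous join),
* the peak value (``peak_amplitude``),
* a stationary maximum at the inspiration fraction of the window.

Peak positions are snapped to the sample grid so the true maximum is a sample
point.  "Steepness" control acts through the edge depth (a deeper drop from
peak to baseline steepens the peak at constant amplitude).

Ground truth is expressed in the *detection frame* of the clean trace: the
interval where the clean signal exceeds the scan line, with the generating
cubic re-expanded over that interval by a pure affine coefficient transform.
If the clean-frame crossings are ``(t0, t1)`` and the nominal window length is
``D``, then with ``beta = (t1 - t0) / D`` the true parameters in the fit's
reversed normalized time are

    b1 = (t1 - t_peak) / (t1 - t0),      b2 = -c3 * beta**3,
    b3 = -(Q''(f)/2) * beta**2,          b4 = 0,    b5 = peak_amplitude,

where Q is the window cubic and c3 its leading coefficient.  Tube-intensity
drift (quadratic baseline, slow gain) and Gaussian detector noise are added
on top of the clean signal and are *not* part of the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .breath_analysis import MIN_EVENT_SAMPLES, _cross_time
from .movie_io import FrameStack, ROISpec, Rect
from .xtf_extract import XTFTrace


@dataclass
class TraceSimConfig:
    """Study conditions of a single simulated scan.

    Defaults follow the acquisition protocol: 1024 samples at 30 Hz and one
    breathing event per 1400 ms.  Each cycle consists of an active breath
    pulse occupying ``active_fraction`` of the cycle followed by an
    end-expiratory baseline (anesthetized mice spend a substantial part of
    each cycle at rest, which is what lets the scan line separate events
    cleanly).  ``inspiration_fraction`` is the relative time to peak within
    the active pulse (the t_in/100 proxy); ``edge_depth`` the depth of the
    inter-breath baseline below zero in units of the peak amplitude;
    ``steepness`` a multiplicative control of the peak-to-baseline drop;
    ``baseline_drift`` ascending quadratic coefficients (per second) of an
    additive drift.
    """

    duration_s: float = 1024 / 30.0
    sample_rate_hz: float = 30.0
    breath_period_ms: float = 1400.0
    active_fraction: float = 0.5
    inspiration_fraction: float = 0.45
    peak_amplitude: float = 1.0
    edge_depth: float = 0.4
    steepness: float = 1.0
    baseline_drift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.02
    pause_ms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.inspiration_fraction < 1.0:
            raise ValueError("inspiration_fraction must lie in (0, 1)")
        for name in ("duration_s", "sample_rate_hz", "breath_period_ms", "peak_amplitude"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or self.pause_ms < 0:
            raise ValueError("noise_sd and pause_ms must be nonnegative")
        if not 0.0 < self.active_fraction <= 1.0:
            raise ValueError("active_fraction must lie in (0, 1]")
        if not self.steepness > 0:
            raise ValueError("steepness must be positive")

    @property
    def effective_edge_depth(self) -> float:
        """Edge depth after the steepness control, clipped away from zero."""
        return max((1.0 + self.edge_depth) * self.steepness - 1.0, 0.05)


@dataclass
class GroundTruthEvent:
    """True parameters of one complete simulated breath, in the detection frame."""

    start_ms: float
    end_ms: float
    peak_time_ms: float
    b1: float
    b2: float
    b3: float
    b4: float
    b5: float
    t_in_pct: float


@dataclass
class GroundTruth:
    """Simulator-side record of the clean trace's complete events."""

    events: list[GroundTruthEvent]
    level: float  # scan line of the clean trace

    @property
    def n_events(self) -> int:
        return len(self.events)

    def mean(self, attr: str) -> float:
        return float(np.mean([getattr(e, attr) for e in self.events]))


@dataclass
class StackSimConfig:
    """Forward model of a radiograph movie around a simulated breathing signal.

    Background pixels carry ``B0 * g(t)``, lung pixels ``B0 * g(t) * (1 + s(t))``
    with s the breathing signal and g a slow linear tube-gain drift of total
    relative amplitude ``tube_gain_drift``; optional Gaussian pixel noise.
    """

    trace: TraceSimConfig = field(default_factory=TraceSimConfig)
    frame_shape: tuple[int, int] = (64, 64)
    lung_rois: tuple[Rect, ...] = (Rect(20, 44, 8, 28), Rect(20, 44, 36, 56))
    background_roi: Rect = Rect(2, 12, 2, 12)
    b0: float = 1000.0
    tube_gain_drift: float = 0.0
    pixel_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        ROISpec(lung_rois=list(self.lung_rois), background_roi=self.background_roi).validate_against(
            self.frame_shape
        )
        if not self.b0 > 0:
            raise ValueError("b0 must be positive")


@dataclass(frozen=True)
class GroupPreset:
    """Per-group physiology: absolute amplitude, inspiration fraction and
    steepness applied to the base trace configuration."""

    amplitude: float
    inspiration_fraction: float
    steepness: float


#: Effect-direction presets.  SAA (allergic inflammation): reduced peak
#: amplitude (b5, less air), reduced steepness (b3, slower gas exchange) and a
#: shorter relative inspiration time (lower t_in, higher b1) than healthy
#: controls; the treated group sits in between, with amplitude closest to CN.
DEFAULT_PRESETS: dict[str, GroupPreset] = {
    "CN": GroupPreset(amplitude=1.0, inspiration_fraction=0.45, steepness=1.0),
    "SAA": GroupPreset(amplitude=0.6, inspiration_fraction=0.35, steepness=0.85),
    "SAA-DEX": GroupPreset(amplitude=0.85, inspiration_fraction=0.41, steepness=0.95),
}


@dataclass
class CohortSimConfig:
    """A simulated cohort: group presets, animals per group and inter-animal
    variability (multiplicative lognormal, physiological positivity)."""

    presets: Mapping[str, GroupPreset] = field(default_factory=lambda: dict(DEFAULT_PRESETS))
    n_per_group: int = 6
    variability_sd: float = 0.08
    base: TraceSimConfig = field(default_factory=TraceSimConfig)
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need n >= 2 animals per group")
        if self.variability_sd < 0:
            raise ValueError("variability_sd must be nonnegative")


def _solve_pulse(f: float, amplitude: float, depth: float) -> np.ndarray:
    """Cubic coefficients (ascending powers on window time x in [0, 1]) with
    Q(0) = Q(1) = -depth*amplitude, Q(f) = amplitude and Q'(f) = 0."""
    if not 0.02 < f < 0.98:
        raise ValueError(f"inspiration fraction {f} too extreme for a cubic pulse")
    edge = -depth * amplitude
    a = np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [1.0, 1.0, 1.0, 1.0],
            [1.0, f, f**2, f**3],
            [0.0, 1.0, 2.0 * f, 3.0 * f**2],
        ]
    )
    rhs = np.array([edge, edge, amplitude, 0.0])
    coeffs = np.linalg.solve(a, rhs)
    if 2.0 * coeffs[2] + 6.0 * coeffs[3] * f >= 0.0:  # Q''(f) must be < 0 (a maximum)
        raise ValueError("pulse solve produced a non-maximum stationary point")
    return coeffs


def _clean_runs(values: np.ndarray, level: float) -> list[tuple[int, int, float, float]]:
    """Maximal strictly-above runs with interpolated crossings (same rules as
    detection: boundary-touching and short runs dropped)."""
    n = values.size
    above = values > level
    runs = []
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        if i > 0 and j < n - 1 and (j - i + 1) >= MIN_EVENT_SAMPLES:
            runs.append((i, j, values[i - 1], values[j + 1]))
        i = j + 1
    return runs


def simulate_trace(cfg: TraceSimConfig) -> tuple[XTFTrace, GroundTruth]:
    """One simulated scan: clean cubic pulses + drift + noise, with ground truth.

    Reproducible given ``cfg.seed``; identical configurations give
    bit-identical traces.
    """
    rate = cfg.sample_rate_hz
    n = int(round(cfg.duration_s * rate))
    dt_ms = 1000.0 / rate
    period_samples = int(round(cfg.breath_period_ms / dt_ms))
    pause_samples = int(round(cfg.pause_ms / dt_ms))
    window_samples = int(round(cfg.active_fraction * (period_samples - pause_samples)))
    if window_samples < MIN_EVENT_SAMPLES:
        raise ValueError("breath period shorter than 5 samples")

    # snap the peak to the sample grid; the quantized fraction is the truth
    peak_offset = int(round(cfg.inspiration_fraction * window_samples))
    peak_offset = min(max(peak_offset, 1), window_samples - 1)
    f_eff = peak_offset / window_samples
    depth = cfg.effective_edge_depth
    coeffs = _solve_pulse(f_eff, cfg.peak_amplitude, depth)
    baseline = -depth * cfg.peak_amplitude

    times = np.arange(n) * dt_ms
    clean = np.full(n, baseline)
    margin = 2  # baseline samples before the first / after the last window
    starts = []
    s = margin
    while s + window_samples <= n - 1 - margin:
        starts.append(s)
        s += period_samples
    window_ms = window_samples * dt_ms
    for s_k in starts:
        idx = np.arange(s_k, s_k + window_samples + 1)
        x = (idx - s_k) / window_samples
        clean[idx] = np.maximum(baseline, np.polynomial.polynomial.polyval(x, coeffs))

    level = float(np.mean(clean)) + 0.33 * float(np.std(clean, ddof=1))
    runs = _clean_runs(clean, level)

    # second-derivative magnitude at the peak, in window-normalized time
    b3_window = -(2.0 * coeffs[2] + 6.0 * coeffs[3] * f_eff) / 2.0
    events: list[GroundTruthEvent] = []
    for (i, j, v_before, v_after) in runs:
        t0 = _cross_time(times[i - 1], times[i], v_before, clean[i], level)
        t1 = _cross_time(times[j], times[j + 1], clean[j], v_after, level)
        dur = t1 - t0
        peaks = [s_k + peak_offset for s_k in starts if i <= s_k + peak_offset <= j]
        if len(peaks) != 1:
            continue  # run not attributable to exactly one pulse
        t_peak = times[peaks[0]]
        beta = dur / window_ms
        events.append(
            GroundTruthEvent(
                start_ms=t0,
                end_ms=t1,
                peak_time_ms=t_peak,
                b1=(t1 - t_peak) / dur,
                b2=-coeffs[3] * beta**3,
                b3=b3_window * beta**2,
                b4=0.0,
                b5=cfg.peak_amplitude,
                t_in_pct=100.0 * (t_peak - t0) / dur,
            )
        )

    value = clean.copy()
    drift = cfg.baseline_drift
    if any(drift):
        t_s = times / 1000.0
        value = value + drift[0] + drift[1] * t_s + drift[2] * t_s**2
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        value = value + rng.normal(0.0, cfg.noise_sd, n)

    trace = XTFTrace(time_ms=times, value=value, detrended=False, source=f"synthetic(seed={cfg.seed})")
    return trace, GroundTruth(events=events, level=level)


def simulate_stack(cfg: StackSimConfig) -> tuple[FrameStack, ROISpec, GroundTruth]:
    """Forward-model a radiograph movie whose XTF reproduces the simulated
    breathing signal (exactly, for zero noise and constant gain)."""
    trace_cfg = replace(cfg.trace, noise_sd=0.0, baseline_drift=(0.0, 0.0, 0.0))
    signal, truth = simulate_trace(trace_cfg)
    s = signal.value
    n = s.size
    t_rel = np.arange(n) / max(n - 1, 1)
    gain = 1.0 + cfg.tube_gain_drift * (t_rel - 0.5)

    h, w = cfg.frame_shape
    frames = np.empty((n, h, w), dtype=np.float64)
    frames[:] = (cfg.b0 * gain)[:, None, None]
    lung_mask = np.zeros(cfg.frame_shape, dtype=bool)
    for roi in cfg.lung_rois:
        lung_mask[roi.as_slices()] = True
    frames[:, lung_mask] = (cfg.b0 * gain * (1.0 + s))[:, None]
    if cfg.pixel_noise_sd > 0:
        rng = np.random.default_rng(cfg.trace.seed)
        frames = frames + rng.normal(0.0, cfg.pixel_noise_sd, frames.shape)
        np.clip(frames, 0.0, None, out=frames)

    stack = FrameStack(frames=frames, frame_rate_hz=cfg.trace.sample_rate_hz)
    rois = ROISpec(lung_rois=list(cfg.lung_rois), background_roi=cfg.background_roi)
    return stack, rois, truth


def simulate_cohort(cfg: CohortSimConfig) -> dict[str, list[tuple[XTFTrace, GroundTruth]]]:
    """Simulate named groups of animals with lognormal inter-animal variability.

    Per animal, amplitude, steepness and inspiration fraction are the group
    preset times independent lognormal(0, variability_sd) draws; each animal's
    scan gets its own noise seed.  Reproducible given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    cohort: dict[str, list[tuple[XTFTrace, GroundTruth]]] = {}
    for name, preset in cfg.presets.items():
        animals = []
        for _ in range(cfg.n_per_group):
            if cfg.variability_sd > 0:
                m_amp, m_steep, m_insp = rng.lognormal(0.0, cfg.variability_sd, 3)
            else:
                m_amp = m_steep = m_insp = 1.0
            animal_cfg = replace(
                cfg.base,
                peak_amplitude=preset.amplitude * m_amp,
                steepness=preset.steepness * m_steep,
                inspiration_fraction=float(
                    np.clip(preset.inspiration_fraction * m_insp, 0.1, 0.9)
                ),
                seed=int(rng.integers(2**31)),
            )
            animals.append(simulate_trace(animal_cfg))
        cohort[name] = animals
    return cohort


@dataclass
class MethacholineSimConfig:
    """Bronchoconstriction ramp: per-dose factors on steepness (airflow) and
    inspiration fraction, paired per animal across doses."""

    doses: tuple[float, ...] = (0.0, 3.0, 10.0, 50.0)
    steepness_factors: tuple[float, ...] = (1.0, 0.95, 0.88, 0.78)
    inspiration_factors: tuple[float, ...] = (1.0, 0.97, 0.94, 0.90)
    n_animals: int = 6
    variability_sd: float = 0.08
    base: TraceSimConfig = field(default_factory=TraceSimConfig)
    seed: int = 1

    def __post_init__(self) -> None:
        if not len(self.doses) == len(self.steepness_factors) == len(self.inspiration_factors):
            raise ValueError("one factor pair per dose required")
        if self.doses[0] != 0.0:
            raise ValueError("first dose must be the 0 mg/ml baseline")
        if self.n_animals < 2:
            raise ValueError("need n >= 2 animals")


def simulate_methacholine(
    cfg: MethacholineSimConfig,
) -> dict[float, list[tuple[XTFTrace, GroundTruth]]]:
    """Simulate one group across a methacholine dose series.

    Animals keep their individual physiology (drawn once) across doses; only
    the dose factors and the scan noise differ, so each animal is its own
    baseline.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.variability_sd > 0:
        mult = rng.lognormal(0.0, cfg.variability_sd, (cfg.n_animals, 3))
    else:
        mult = np.ones((cfg.n_animals, 3))
    scan_seeds = rng.integers(2**31, size=(len(cfg.doses), cfg.n_animals))
    out: dict[float, list[tuple[XTFTrace, GroundTruth]]] = {}
    for d, (dose, sf, insp_f) in enumerate(
        zip(cfg.doses, cfg.steepness_factors, cfg.inspiration_factors)
    ):
        animals = []
        for a in range(cfg.n_animals):
            animal_cfg = replace(
                cfg.base,
                peak_amplitude=cfg.base.peak_amplitude * mult[a, 0],
                steepness=cfg.base.steepness * mult[a, 1] * sf,
                inspiration_fraction=float(
                    np.clip(cfg.base.inspiration_fraction * mult[a, 2] * insp_f, 0.1, 0.9)
                ),
                seed=int(scan_seeds[d, a]),
            )
            animals.append(simulate_trace(animal_cfg))
        out[float(dose)] = animals
    return out
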