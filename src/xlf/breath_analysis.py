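"""Breathing-event detection and cubic-peak parameterization.

Breaths are found as maximal runs of the (detrended) XTF strictly above a
scan line at ``mean + 0.33 * SD``; the run boundaries are refined to linearly
interpolated level crossings.  Each event is then described by a shifted
third-order polynomial

    P(x) = b2*(x - b1)**3 - b3*(x - b1)**2 - b4*(x - b1) + b5

on normalized event time.  ``x`` runs 1 -> 0 from event start to event end
(reversed normalized time), so that ``b1`` -- the shift of the peak maximum --
*increases* when the breathing peak moves earlier in the event, i.e. when the
relative inspiration time shortens, as it does under expiratory airflow
limitation.  The relative inspiration time is reported separately as
``t_in[%] = 100 * (1 - b1)``.

All parameters are unitless because the XTF is.  Interpretation: b1 peak
position (inhalation/exhalation ratio), b2/b4 asymmetry of the peak, b3
steepness of the peak (dynamic of gas exchange), b5 the peak maximum
(maximum air content in the lung).

A joint 5-parameter fit of P would be underdetermined (a cubic has four
degrees of freedom), so the fit is staged and deterministic: b1 starts at the
normalized position of the maximum sample, the remaining four coefficients
are ordinary least squares, and b1 is then refined once to the fitted
cubic's stationary maximum (exact when the true peak lies on a sample;
removes the multi-sample argmax jitter that detector noise causes on flat
peaks).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .movie_io import TraceRecord
from .xtf_extract import XTFTrace


class DegenerateTraceError(ValueError):
    """Constant trace: scan line undefined."""


class UnfittableEventError(ValueError):
    """Event whose samples do not determine the cubic (e.g. all equal)."""


class NoBreathsError(ValueError):
    """No breathing events to summarize."""


class SamplingRateError(ValueError):
    """Sampling rate too low for the requested band-pass."""


MIN_EVENT_SAMPLES = 5  # interior samples; a cubic fit needs >= 5 points for a residual


@dataclass
class BreathEvent:
    """One detected breathing cycle.

    ``sample_times_ms``/``sample_values`` hold the samples strictly above the
    scan line plus the two interpolated boundary crossings (first and last
    entry, at the scan-line level).  The crossings define the event bounds and
    duration; the cubic fit uses the interior samples only.
    """

    start_ms: float
    end_ms: float
    sample_times_ms: np.ndarray
    sample_values: np.ndarray
    level: float

    def __post_init__(self) -> None:
        self.sample_times_ms = np.asarray(self.sample_times_ms, dtype=float)
        self.sample_values = np.asarray(self.sample_values, dtype=float)
        if not self.end_ms > self.start_ms:
            raise ValueError("event end must be after start")
        if self.sample_times_ms.size < MIN_EVENT_SAMPLES:
            raise ValueError("event with fewer than 5 samples")
        if np.any(self.sample_values[1:-1] <= self.level):
            raise ValueError("interior sample at or below scan line")

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass
class BreathParams:
    """Fitted shifted-cubic parameters of one breathing event (all unitless
    except the duration)."""

    b1: float
    b2: float
    b3: float
    b4: float
    b5: float
    t_in_pct: float
    duration_ms: float
    peak_amplitude: float  # event maximum above the scan line

    def __post_init__(self) -> None:
        if not 0.0 < self.b1 < 1.0:
            raise ValueError(f"b1 must lie in (0, 1), got {self.b1}")
        if not 0.0 < self.t_in_pct < 100.0:
            raise ValueError(f"t_in_pct must lie in (0, 100), got {self.t_in_pct}")
        if not self.duration_ms > 0:
            raise ValueError("duration must be positive")


@dataclass
class ScanSummary:
    """Per-scan averages of breath parameters plus rate and slope metrics."""

    mean_b1: float
    mean_b2: float
    mean_b3: float
    mean_b4: float
    mean_b5: float
    mean_t_in_pct: float
    n_events: int
    bpm: float
    max_slope: float
    min_slope: float
    peak_amplitude: float


def scan_line_level(trace: XTFTrace) -> float:
    """Detection threshold: mean + 0.33 * sample standard deviation (n-1)."""
    if len(trace) < 2:
        raise DegenerateTraceError("trace too short for a scan line")
    sd = float(np.std(trace.value, ddof=1))
    if sd == 0.0:
        raise DegenerateTraceError("degenerate trace: zero standard deviation")
    return float(np.mean(trace.value)) + 0.33 * sd


def _cross_time(t0: float, t1: float, v0: float, v1: float, level: float) -> float:
    """Linearly interpolated time at which the segment (t0,v0)-(t1,v1) crosses level."""
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def detect_breaths(trace: XTFTrace, level: float) -> list[BreathEvent]:
    """Maximal runs of samples strictly above ``level``, with interpolated bounds.

    Runs touching the first or last sample are incomplete breaths and are
    discarded, as are runs with fewer than 5 interior samples (noise guard).
    """
    t = trace.time_ms
    v = trace.value
    n = v.size
    above = v > level
    events: list[BreathEvent] = []
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        if i > 0 and j < n - 1 and (j - i + 1) >= MIN_EVENT_SAMPLES:
            start = _cross_time(t[i - 1], t[i], v[i - 1], v[i], level)
            end = _cross_time(t[j], t[j + 1], v[j], v[j + 1], level)
            events.append(
                BreathEvent(
                    start_ms=start,
                    end_ms=end,
                    sample_times_ms=np.concatenate(([start], t[i : j + 1], [end])),
                    sample_values=np.concatenate(([level], v[i : j + 1], [level])),
                    level=level,
                )
            )
        i = j + 1
    return events


def fit_breath(event: BreathEvent) -> BreathParams:
    """Fit the shifted cubic to one event; deterministic staged scheme.

    (1) Map interior sample times to reversed normalized time
    ``x = (end - t) / duration`` in [0, 1].  (2) Set b1 to the x-position of
    the maximum sample (time ties broken toward the earlier sample).  (3) With
    b1 fixed, estimate (b2, b3, b4, b5) by ordinary least squares on the basis
    ``{(x-b1)^3, -(x-b1)^2, -(x-b1), 1}``.  (4) Refine b1 once to the fitted
    cubic's stationary maximum if that lies inside the event, and re-estimate
    the coefficients.  ``t_in[%] = 100 * (1 - b1)``.

    The refinement is an exact no-op for noiseless data sampled from the
    model with the peak on a sample, so exact recovery is preserved; under
    detector noise it replaces the multi-sample jitter of the raw argmax by
    the far steadier stationary point of the full-event fit.
    """
    t = event.sample_times_ms[1:-1]
    v = event.sample_values[1:-1]
    if np.ptp(v) == 0.0:
        raise UnfittableEventError("unfittable event: all samples equal")

    x = (event.end_ms - t) / event.duration_ms  # reversed normalized time
    i_max = int(np.argmax(v))  # first occurrence = earliest in time
    b1 = float(x[i_max])
    b2, b3, b4, b5 = _ls_coeffs(x, v, b1)
    refined = _stationary_maximum(b1, b2, b3, b4)
    if refined is not None and 0.0 < refined < 1.0:
        b1 = refined
        b2, b3, b4, b5 = _ls_coeffs(x, v, b1)

    return BreathParams(
        b1=b1,
        b2=b2,
        b3=b3,
        b4=b4,
        b5=b5,
        t_in_pct=100.0 * (1.0 - b1),
        duration_ms=event.duration_ms,
        peak_amplitude=float(v.max() - event.level),
    )


def _ls_coeffs(x: np.ndarray, v: np.ndarray, b1: float) -> tuple[float, float, float, float]:
    u = x - b1
    design = np.column_stack((u**3, -(u**2), -u, np.ones_like(u)))
    coeffs, _, rank, _ = np.linalg.lstsq(design, v, rcond=None)
    if rank < 4:
        raise UnfittableEventError("unfittable event: degenerate design matrix")
    return tuple(float(c) for c in coeffs)


def _stationary_maximum(b1: float, b2: float, b3: float, b4: float) -> float | None:
    """x-position of the fitted cubic's interior maximum, or None.

    P'(x) = 3*b2*u^2 - 2*b3*u - b4 with u = x - b1; a root with P'' < 0.
    """
    if b2 == 0.0:
        if b3 <= 0.0:
            return None
        u = -b4 / (2.0 * b3)  # parabola vertex
        return b1 + u
    disc = b3**2 + 3.0 * b2 * b4
    if disc < 0.0:
        return None
    roots = (b3 + np.sqrt(disc)) / (3.0 * b2), (b3 - np.sqrt(disc)) / (3.0 * b2)
    for u in roots:
        if 6.0 * b2 * u - 2.0 * b3 < 0.0:  # P'' < 0: a maximum
            return b1 + float(u)
    return None


def slope_metrics(trace: XTFTrace | TraceRecord) -> tuple[float, float]:
    """(max_slope, min_slope): extrema of the first central-difference
    derivative of the trace, in value per second."""
    grad = np.gradient(np.asarray(trace.value, float), np.asarray(trace.time_ms, float) / 1000.0)
    return float(grad.max()), float(grad.min())


def summarize_scan(events: Sequence[BreathParams], trace: XTFTrace) -> ScanSummary:
    """Arithmetic means of the per-event parameters plus BPM and slope metrics.

    BPM uses the covered trace duration (span plus one sample interval).
    """
    if not events:
        raise NoBreathsError("no breaths detected")
    max_slope, min_slope = slope_metrics(trace)
    duration_min = trace.duration_ms / 60000.0
    return ScanSummary(
        mean_b1=float(np.mean([e.b1 for e in events])),
        mean_b2=float(np.mean([e.b2 for e in events])),
        mean_b3=float(np.mean([e.b3 for e in events])),
        mean_b4=float(np.mean([e.b4 for e in events])),
        mean_b5=float(np.mean([e.b5 for e in events])),
        mean_t_in_pct=float(np.mean([e.t_in_pct for e in events])),
        n_events=len(events),
        bpm=len(events) / duration_min,
        max_slope=max_slope,
        min_slope=min_slope,
        peak_amplitude=float(np.mean([e.peak_amplitude for e in events])),
    )


def analyze_trace(
    trace: XTFTrace, level: float | None = None
) -> tuple[float, list[BreathEvent], list[BreathParams], ScanSummary]:
    """Full per-scan analysis: scan line, detection, per-event fits, summary."""
    if level is None:
        level = scan_line_level(trace)
    events = detect_breaths(trace, level)
    params = [fit_breath(e) for e in events]
    summary = summarize_scan(params, trace)
    return level, events, params, summary


def bandpass_trace(
    trace: TraceRecord, low_hz: float = 0.5, high_hz: float = 20.0
) -> TraceRecord:
    """Zero-phase 4th-order Butterworth band-pass (plethysmography preprocessing).

    The mean is removed before filtering, so a constant input maps to zero
    exactly and the output is DC-free.
    """
    dt_ms = float(np.median(np.diff(trace.time_ms)))
    fs = 1000.0 / dt_ms
    if fs <= 2.0 * high_hz:
        raise SamplingRateError(
            f"sampling rate {fs:.3g} Hz too low for a {high_hz:.3g} Hz band edge"
        )
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, trace.value - np.mean(trace.value))
    return TraceRecord(time_ms=trace.time_ms, value=filtered, label=trace.label)
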