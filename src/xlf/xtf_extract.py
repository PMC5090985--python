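"""X-ray transmission function (XTF) extraction and detrending.

The XTF is the central signal of the method: for each movie frame the mean
transmission of the pooled lung ROIs, minus the mean background transmission,
normalized by the *time-averaged* background,

    XTF(t_k) = (L(t_k) - B(t_k)) / <B>,

which makes the signal unitless and cancels x-ray tube intensity fluctuations.
Internally the ratio is evaluated in a single-division exact-sum form

    XTF(t_k) = T * (aB * SL_k - aL * SB_k) / (aL * sum_k SB_k),

where SL/SB are ROI pixel sums and aL/aB the ROI areas.  For integer-valued
detector counts every term is exact in float64, so a constant detector gain g
cancels bit-for-bit -- rescaling the stack cannot change the XTF at all.

Residual slow drift (tube warm-up, anesthesia depth) is removed by smoothing
with a centered moving average and subtracting a low-order polynomial trend.
The polynomial is fitted on the filter's interior (where no boundary padding
enters) and the uniform filter's known action on polynomials is inverted
before subtraction, so a polynomial input of degree <= the fit order is
annihilated to machine precision and the operation is exactly idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np

from .movie_io import FrameStack, MovieIOError, ROISpec, Rect, TraceRecord


class DegenerateBackgroundError(MovieIOError):
    """Time-averaged background signal is zero; XTF undefined."""


@dataclass
class XTFTrace:
    """Unitless transmission-vs-time series (raw or detrended)."""

    time_ms: np.ndarray
    value: np.ndarray
    detrended: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_ms.shape != self.value.shape or self.time_ms.ndim != 1:
            raise ValueError("time and value must be 1-D and of equal length")
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("times not strictly increasing")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("non-finite XTF value")

    def __len__(self) -> int:
        return int(self.value.size)

    @property
    def sample_interval_ms(self) -> float:
        return float(np.median(np.diff(self.time_ms)))

    @property
    def duration_ms(self) -> float:
        """Covered duration: time span plus one sample interval."""
        return float(self.time_ms[-1] - self.time_ms[0]) + self.sample_interval_ms

    def to_record(self) -> TraceRecord:
        return TraceRecord(time_ms=self.time_ms, value=self.value, label=self.source)

    @classmethod
    def from_record(cls, rec: TraceRecord, detrended: bool = False) -> "XTFTrace":
        return cls(time_ms=rec.time_ms, value=rec.value, detrended=detrended, source=rec.label)


@dataclass
class DetrendConfig:
    """Moving-average window (samples) and polynomial order of the drift model."""

    window: int = 200
    poly_order: int = 2

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not 0 <= self.poly_order <= 5:
            raise ValueError("poly_order must be in 0..5")


def _union_mask(frame_shape: tuple[int, int], rois: Rect | Sequence[Rect]) -> np.ndarray:
    if isinstance(rois, Rect):
        rois = [rois]
    mask = np.zeros(frame_shape, dtype=bool)
    for roi in rois:
        if not roi.within(frame_shape):
            raise MovieIOError(f"ROI outside frame: {roi.to_list()} vs {frame_shape}")
        mask[roi.as_slices()] = True
    if not mask.any():
        raise MovieIOError("empty ROI union")
    return mask


def mean_transmission(stack: FrameStack, rois: Rect | Sequence[Rect]) -> np.ndarray:
    """Per-frame arithmetic mean over the union of the given rectangles."""
    mask = _union_mask(stack.frame_shape, rois)
    return stack.frames[:, mask].sum(axis=1, dtype=np.float64) / int(mask.sum())


def compute_xtf(stack: FrameStack, rois: ROISpec) -> XTFTrace:
    """Raw (not detrended) XTF of a stack given lung and background ROIs.

    Left/right lung ROIs are pooled into one area-weighted mean, yielding one
    XTF per scan.
    """
    rois.validate_against(stack.frame_shape)
    lung_mask = _union_mask(stack.frame_shape, rois.lung_rois)
    bkg_mask = _union_mask(stack.frame_shape, rois.background_roi)
    a_l = int(lung_mask.sum())
    a_b = int(bkg_mask.sum())
    s_l = stack.frames[:, lung_mask].sum(axis=1, dtype=np.float64)
    s_b = stack.frames[:, bkg_mask].sum(axis=1, dtype=np.float64)
    ssb = float(s_b.sum())
    if ssb == 0.0:
        raise DegenerateBackgroundError("degenerate background: time-averaged background is zero")
    t = stack.n_frames
    xtf = (t * (a_b * s_l - a_l * s_b)) / (a_l * ssb)
    return XTFTrace(
        time_ms=stack.frame_times_ms,
        value=xtf,
        detrended=False,
        source="compute_xtf",
    )


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with reflect padding; output length equals input.

    For even windows the center sits half a sample late (offsets
    ``-(w-1)//2 .. w//2``); :func:`detrend_xtf` accounts for the resulting
    window moments exactly.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if window > n:
        raise ValueError(f"trace shorter than window ({n} < {window})")
    if window == 1:
        return values.copy()
    left = (window - 1) // 2
    right = window // 2
    padded = np.pad(values, (left, right), mode="reflect")
    return np.convolve(padded, np.full(window, 1.0 / window), mode="valid")


def _window_moment_matrix(window: int, dt_s: float, order: int) -> np.ndarray:
    """Matrix of the uniform filter's action on polynomial coefficients.

    The moving average maps a polynomial ``p(t)`` to ``mean_j p(t + d_j)``
    with offsets ``d_j = j * dt`` for ``j = -(w-1)//2 .. w//2``.  On ascending
    power-basis coefficients this is the upper-triangular map
    ``M[m, k] = C(k, m) * mu_{k-m}`` with ``mu_q`` the q-th raw moment of the
    offsets.  Its inverse recovers the true trend from the fit to the
    smoothed series.
    """
    left = (window - 1) // 2
    offsets = np.arange(-left, window - left) * dt_s
    mu = [float(np.mean(offsets**q)) for q in range(order + 1)]
    m = np.zeros((order + 1, order + 1))
    for k in range(order + 1):
        for mm in range(k + 1):
            m[mm, k] = comb(k, mm) * mu[k - mm]
    return m


def detrend_xtf(trace: XTFTrace, cfg: DetrendConfig | None = None) -> XTFTrace:
    """Subtract the slow polynomial drift from an XTF trace.

    Steps: (1) centered moving average of the XTF; (2) least-squares
    polynomial fit (in seconds, centered at the trace midpoint) on the
    filter's interior samples; (3) inversion of the filter's polynomial
    moment map; (4) subtraction of the recovered trend from the *original*
    XTF.  Degree <= ``poly_order`` inputs are annihilated exactly and the
    operation is idempotent.
    """
    if cfg is None:
        cfg = DetrendConfig()
    n = len(trace)
    if n < cfg.window:
        raise ValueError(f"trace shorter than window ({n} < {cfg.window})")
    smoothed = moving_average(trace.value, cfg.window)
    left = (cfg.window - 1) // 2
    right = cfg.window // 2
    interior = slice(left, n - right)
    if (n - right) - left < cfg.poly_order + 1:
        raise ValueError("too few interior samples for the polynomial fit")

    t_s = (trace.time_ms - trace.time_ms[n // 2]) / 1000.0
    coeffs = np.polynomial.polynomial.polyfit(t_s[interior], smoothed[interior], cfg.poly_order)
    dt_s = trace.sample_interval_ms / 1000.0
    m = _window_moment_matrix(cfg.window, dt_s, cfg.poly_order)
    trend_coeffs = np.linalg.solve(m, coeffs)
    trend = np.polynomial.polynomial.polyval(t_s, trend_coeffs)
    return XTFTrace(
        time_ms=trace.time_ms,
        value=trace.value - trend,
        detrended=True,
        source=trace.source,
    )
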