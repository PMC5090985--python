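"""Reading and writing of cinematic radiograph stacks, ROI specifications and
breathing traces.

The on-disk formats are deliberately plain:

* multi-page TIFF for frame stacks (frame rate stored as a JSON fragment in
  the TIFF description tag, or supplied by the caller);
* JSON for ROI specifications, with 0-based half-open ``[row0, row1, col0,
  col1]`` rectangles;
* CSV with header ``time_ms,value`` for traces, written with 17 significant
  digits so that a write/read cycle is lossless for float64.

Frame times are uniform, ``t_k = k / frame_rate_hz``; there is no silent
default frame rate -- a stack without one is an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile


class MovieIOError(ValueError):
    """Base class for movie/trace I/O and validation failures."""


class StackTooShortError(MovieIOError):
    """Fewer than two frames in a stack."""


class InconsistentFrameShapeError(MovieIOError):
    """Pages of a multi-page TIFF do not share one shape."""


class MissingFrameRateError(MovieIOError):
    """No frame rate supplied and none found in the file metadata."""


class ROIValidationError(MovieIOError):
    """Degenerate, out-of-bounds or overlapping region of interest."""


class TraceFormatError(MovieIOError):
    """Malformed trace file or trace with non-increasing times."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle, 0-based, half-open ``[row0, row1) x [col0, col1)``."""

    row0: int
    row1: int
    col0: int
    col1: int

    def __post_init__(self) -> None:
        for v in (self.row0, self.row1, self.col0, self.col1):
            if int(v) != v:
                raise ROIValidationError(f"rectangle bounds must be integers, got {v!r}")
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ROIValidationError(f"empty rectangle {self.to_list()}")
        if self.row0 < 0 or self.col0 < 0:
            raise ROIValidationError(f"negative rectangle origin {self.to_list()}")

    @property
    def area(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)

    def as_slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)

    def overlaps(self, other: "Rect") -> bool:
        return (
            self.row0 < other.row1
            and other.row0 < self.row1
            and self.col0 < other.col1
            and other.col0 < self.col1
        )

    def within(self, frame_shape: tuple[int, int]) -> bool:
        return self.row1 <= frame_shape[0] and self.col1 <= frame_shape[1]

    def to_list(self) -> list[int]:
        return [self.row0, self.row1, self.col0, self.col1]

    @classmethod
    def from_list(cls, values: Sequence[int]) -> "Rect":
        if len(values) != 4:
            raise ROIValidationError(f"rectangle needs 4 entries, got {values!r}")
        return cls(*(int(v) for v in values))


@dataclass
class FrameStack:
    """Ordered 2-D transmission frames with frame-rate metadata.

    ``frames`` is a ``T x H x W`` array of nonnegative detector intensities in
    arbitrary units; ``frame_rate_hz`` the (required, positive) acquisition
    rate.
    """

    frames: np.ndarray
    frame_rate_hz: float
    pixel_spacing_mm: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise MovieIOError(f"frames must be T x H x W, got ndim={self.frames.ndim}")
        if self.frames.shape[0] < 2:
            raise StackTooShortError("stack too short: need at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise MovieIOError("non-finite intensity in stack")
        if np.any(self.frames < 0):
            raise MovieIOError("negative intensity in stack")
        if not self.frame_rate_hz > 0:
            raise MissingFrameRateError(f"frame rate must be positive, got {self.frame_rate_hz}")
        if self.pixel_spacing_mm is not None and not self.pixel_spacing_mm > 0:
            raise MovieIOError("pixel spacing must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return int(self.frames.shape[1]), int(self.frames.shape[2])

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def frame_times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * (1000.0 / self.frame_rate_hz)


@dataclass
class ROISpec:
    """Lung ROIs (one per lobe, kept separate on disk) plus one background ROI."""

    lung_rois: list[Rect]
    background_roi: Rect

    def __post_init__(self) -> None:
        if not self.lung_rois:
            raise ROIValidationError("need at least one lung ROI")
        for roi in self.lung_rois:
            if self.background_roi.overlaps(roi):
                raise ROIValidationError("background overlaps lung ROI")

    def validate_against(self, frame_shape: tuple[int, int]) -> None:
        for roi in [*self.lung_rois, self.background_roi]:
            if not roi.within(frame_shape):
                raise ROIValidationError(
                    f"ROI outside frame: {roi.to_list()} vs frame {frame_shape}"
                )


@dataclass
class TraceRecord:
    """A time series on disk: strictly increasing times (ms) and finite values."""

    time_ms: np.ndarray
    value: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_ms.shape != self.value.shape or self.time_ms.ndim != 1:
            raise TraceFormatError("time and value must be 1-D and of equal length")
        if self.time_ms.size and self.time_ms[0] < 0:
            raise TraceFormatError("times must be nonnegative")
        if np.any(np.diff(self.time_ms) <= 0):
            raise TraceFormatError("times not strictly increasing")
        if not np.all(np.isfinite(self.value)):
            raise TraceFormatError("non-finite value in trace")


def read_stack(path: str | Path, frame_rate_hz: float | None = None) -> FrameStack:
    """Read a multi-page TIFF as a :class:`FrameStack`.

    The frame rate is taken from the ``frame_rate_hz`` argument if given,
    otherwise from a JSON fragment in the TIFF description (as written by
    :func:`write_stack`) or from ImageJ ``fps`` metadata.  A stack without any
    of these is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    with tifffile.TiffFile(path) as tif:
        pages = tif.pages
        n = len(pages)
        if n < 2:
            raise StackTooShortError(f"stack too short: {n} page(s) in {path}")
        shapes = {tuple(p.shape) for p in pages}
        if len(shapes) != 1:
            raise InconsistentFrameShapeError(f"inconsistent page shapes {sorted(shapes)} in {path}")
        frames = tif.asarray()
        if frames.ndim == 2:  # defensive; n >= 2 should give 3-D
            frames = frames[None]
        rate = frame_rate_hz
        if rate is None:
            rate = _rate_from_metadata(tif)
    if rate is None:
        raise MissingFrameRateError(
            f"missing frame rate: none supplied and none found in metadata of {path}"
        )
    return FrameStack(frames=frames, frame_rate_hz=float(rate))


def _rate_from_metadata(tif: "tifffile.TiffFile") -> float | None:
    desc = tif.pages[0].description or ""
    try:
        meta = json.loads(desc)
        if isinstance(meta, dict) and "frame_rate_hz" in meta:
            return float(meta["frame_rate_hz"])
    except (json.JSONDecodeError, TypeError, ValueError):
        pass
    ij = tif.imagej_metadata
    if ij:
        if "fps" in ij:
            return float(ij["fps"])
        if ij.get("finterval"):
            return 1.0 / float(ij["finterval"])
    return None


def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF with the frame rate in the description tag."""
    meta = {"frame_rate_hz": stack.frame_rate_hz}
    if stack.pixel_spacing_mm is not None:
        meta["pixel_spacing_mm"] = stack.pixel_spacing_mm
    # explicit photometric: short stacks must not be guessed as RGB samples
    tifffile.imwrite(
        Path(path), stack.frames, description=json.dumps(meta), photometric="minisblack"
    )


def load_roi_spec(path: str | Path, frame_shape: tuple[int, int] | None = None) -> ROISpec:
    """Load and validate an ROI specification from JSON.

    Expected keys: ``lung_rois`` (list of ``[row0,row1,col0,col1]``) and
    ``background_roi``.  When ``frame_shape`` is given, bounds are checked
    against it.
    """
    with open(path) as fh:
        doc = json.load(fh)
    try:
        lungs = [Rect.from_list(r) for r in doc["lung_rois"]]
        bkg = Rect.from_list(doc["background_roi"])
    except KeyError as exc:
        raise ROIValidationError(f"missing key in ROI spec: {exc}") from exc
    spec = ROISpec(lung_rois=lungs, background_roi=bkg)
    if frame_shape is not None:
        spec.validate_against(frame_shape)
    return spec


def save_roi_spec(spec: ROISpec, path: str | Path) -> None:
    doc = {
        "lung_rois": [r.to_list() for r in spec.lung_rois],
        "background_roi": spec.background_roi.to_list(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def write_trace(trace: TraceRecord, path: str | Path) -> None:
    """Write a trace as ``time_ms,value`` CSV (17 significant digits)."""
    with open(path, "w") as fh:
        if trace.label:
            fh.write(f"# label: {trace.label}\n")
        pd.DataFrame({"time_ms": trace.time_ms, "value": trace.value}).to_csv(
            fh, index=False, float_format="%.17g"
        )


def read_trace(path: str | Path) -> TraceRecord:
    """Read a ``time_ms,value`` CSV back into a :class:`TraceRecord`."""
    path = Path(path)
    label = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# label:"):
            label = first[len("# label:"):].strip()
    try:
        df = pd.read_csv(path, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TraceFormatError(f"malformed trace file {path}: {exc}") from exc
    if list(df.columns) != ["time_ms", "value"]:
        raise TraceFormatError(f"expected header time_ms,value in {path}, got {list(df.columns)}")
    if df.isna().any().any():
        raise TraceFormatError(f"malformed rows in {path}")
    return TraceRecord(
        time_ms=df["time_ms"].to_numpy(float),
        value=df["value"].to_numpy(float),
        label=label,
    )
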