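"""VOI-based quantification of phase-contrast lung CT volumes.

Operates on 3-D volumes of delta-values (the real part of the complex
refractive index, as produced by propagation-based phase-contrast micro-CT at
9 um voxel size).  Within axis-aligned cubic volumes of interest (2 x 2 x 2 mm
by default, eight per lung), voxels are split into air and non-air by a
threshold (Otsu on the global histogram, or a manual value), giving

* ``vol_ratio``  -- the soft-tissue volume fraction (non-air voxels / VOI voxels),
* ``mean_delta`` -- the mean delta-value of the soft-tissue compartment
  (undefined, reported as NaN, for an all-air VOI).

Automatic VOI placement in the peripheral lung is a deterministic greedy
procedure over a regular candidate grid restricted to the outer shell of the
lung mask (outer 30% by distance-to-boundary); manually supplied VOIs (JSON)
are the primary path.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu


class VOIError(ValueError):
    """Invalid VOI geometry (overlap, out of bounds, empty)."""


@dataclass
class Volume3D:
    """3-D array of delta-proportional voxel values with isotropic voxel size."""

    voxels: np.ndarray
    voxel_size_um: float = 9.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"volume must be 3-D, got ndim={self.voxels.ndim}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("non-finite voxel value")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel size must be positive")


@dataclass(frozen=True)
class VOIBox:
    """Axis-aligned cube: 0-based origin (z, y, x) and edge length in voxels."""

    origin: tuple[int, int, int]
    edge: int

    def __post_init__(self) -> None:
        if self.edge < 1:
            raise VOIError("VOI edge must be >= 1 voxel")
        if any(o < 0 for o in self.origin):
            raise VOIError(f"negative VOI origin {self.origin}")

    def as_slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(o, o + self.edge) for o in self.origin)

    def inside(self, shape: tuple[int, int, int]) -> bool:
        return all(o + self.edge <= s for o, s in zip(self.origin, shape))

    def overlaps(self, other: "VOIBox") -> bool:
        return all(
            a < b + other.edge and b < a + self.edge
            for a, b in zip(self.origin, other.origin)
        )


@dataclass
class VOIQuantResult:
    """Per-VOI soft-tissue fraction and mean delta, plus aggregates.

    ``mean_delta`` entries are NaN for VOIs without any non-air voxel;
    ``mean_delta_overall`` averages the defined entries only.
    """

    vol_ratio: np.ndarray
    mean_delta: np.ndarray
    threshold: float
    vol_ratio_overall: float
    mean_delta_overall: float


def _validate_vois(vol: Volume3D, vois: Sequence[VOIBox]) -> None:
    shape = vol.voxels.shape
    for voi in vois:
        if not voi.inside(shape):
            raise VOIError(f"VOI outside volume: origin {voi.origin}, edge {voi.edge}")
    for i in range(len(vois)):
        for j in range(i + 1, len(vois)):
            if vois[i].overlaps(vois[j]):
                raise VOIError(f"overlapping VOIs at indices {i} and {j}")


def quantify_vois(
    vol: Volume3D, vois: Sequence[VOIBox], threshold: float | str = "otsu"
) -> VOIQuantResult:
    """Threshold-segment each VOI into air and non-air and quantify it.

    Non-air (soft tissue and liquids) means voxel value strictly above the
    threshold.  ``threshold="otsu"`` derives one threshold from the global
    volume histogram; a float applies as-is.
    """
    if not vois:
        raise VOIError("no VOIs given")
    _validate_vois(vol, vois)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        thr = float(threshold_otsu(vol.voxels))
    else:
        thr = float(threshold)
    ratios = np.empty(len(vois))
    deltas = np.empty(len(vois))
    for k, voi in enumerate(vois):
        sub = vol.voxels[voi.as_slices()]
        tissue = sub > thr
        n_tissue = int(tissue.sum())
        ratios[k] = n_tissue / sub.size
        deltas[k] = float(sub[tissue].mean()) if n_tissue else np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN aggregate allowed
        overall_delta = float(np.nanmean(deltas))
    return VOIQuantResult(
        vol_ratio=ratios,
        mean_delta=deltas,
        threshold=thr,
        vol_ratio_overall=float(ratios.mean()),
        mean_delta_overall=overall_delta,
    )


def place_vois(
    vol: Volume3D, lung_mask: np.ndarray, n: int = 8, edge_mm: float = 2.0
) -> list[VOIBox]:
    """Deterministic greedy placement of ``n`` non-overlapping cubes in the
    peripheral lung.

    Candidate cube positions lie on a regular grid (stride = half the edge)
    whose cube centers fall in the peripheral shell of the mask -- the outer
    30% by Euclidean distance to the mask boundary.  Candidates are ranked by
    the in-mask fraction of their cube (ties broken by origin), and accepted
    greedily while non-overlapping.  Returns fewer than ``n`` boxes, with a
    warning, if the mask cannot host them.
    """
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if lung_mask.shape != vol.voxels.shape:
        raise VOIError("mask shape must match volume shape")
    if not lung_mask.any():
        warnings.warn("empty lung mask: no VOIs placed", stacklevel=2)
        return []
    edge = int(round(edge_mm * 1000.0 / vol.voxel_size_um))
    shape = vol.voxels.shape
    if edge < 1 or any(edge > s for s in shape):
        warnings.warn("VOI edge does not fit into the volume: no VOIs placed", stacklevel=2)
        return []

    dist = ndimage.distance_transform_edt(lung_mask)
    shell = lung_mask & (dist <= 0.3 * dist.max())

    stride = max(1, edge // 2)
    half = edge // 2
    candidates: list[tuple[float, tuple[int, int, int]]] = []
    in_mask_fraction = ndimage.uniform_filter(lung_mask.astype(float), size=edge)
    for oz in range(0, shape[0] - edge + 1, stride):
        for oy in range(0, shape[1] - edge + 1, stride):
            for ox in range(0, shape[2] - edge + 1, stride):
                cz, cy, cx = oz + half, oy + half, ox + half
                if not shell[cz, cy, cx]:
                    continue
                candidates.append((float(in_mask_fraction[cz, cy, cx]), (oz, oy, ox)))
    candidates.sort(key=lambda c: (-c[0], c[1]))

    placed: list[VOIBox] = []
    for _, origin in candidates:
        box = VOIBox(origin=origin, edge=edge)
        if any(box.overlaps(p) for p in placed):
            continue
        placed.append(box)
        if len(placed) == n:
            break
    if len(placed) < n:
        warnings.warn(f"only {len(placed)} of {n} VOIs placeable", stacklevel=2)
    return placed


def read_volume(path: str | Path, voxel_size_um: float | None = None) -> Volume3D:
    """Read a multi-page TIFF as a delta-value volume."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        voxels = tif.asarray()
        if voxel_size_um is None:
            desc = tif.pages[0].description or ""
            try:
                voxel_size_um = float(json.loads(desc).get("voxel_size_um", 9.0))
            except (json.JSONDecodeError, AttributeError, TypeError, ValueError):
                voxel_size_um = 9.0
    return Volume3D(voxels=voxels, voxel_size_um=voxel_size_um)


def write_volume(vol: Volume3D, path: str | Path) -> None:
    tifffile.imwrite(
        Path(path), vol.voxels, description=json.dumps({"voxel_size_um": vol.voxel_size_um})
    )


def load_vois(path: str | Path) -> list[VOIBox]:
    """Load a JSON list of ``{"origin": [z, y, x], "edge": e}`` boxes."""
    with open(path) as fh:
        doc = json.load(fh)
    return [VOIBox(origin=tuple(int(v) for v in item["origin"]), edge=int(item["edge"])) for item in doc]


def save_vois(vois: Sequence[VOIBox], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([{"origin": list(v.origin), "edge": v.edge} for v in vois], fh, indent=2)
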