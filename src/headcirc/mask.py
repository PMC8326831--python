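"""Outer-skin head mask extraction from an intensity volume.

The measurement only needs the outer scalp boundary, so extraction is
intensity-driven: Otsu threshold, in-plane morphological closing, largest
3D connected component, then slice-wise hole filling so each axial slice's
foreground is simply connected wherever the head is present.  Interior
anatomy (ventricles, sinuses) is irrelevant once holes are filled; any
residual boundary bias is absorbed by the phantom-derived correction
factors, exactly as the calibration protocol intends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk

from .volume import VoxelVolume

__all__ = [
    "BinaryMask",
    "ExtractionError",
    "threshold_value",
    "extract_head_mask",
    "mask_from_threshold",
]


class ExtractionError(ValueError):
    """Mask extraction failed (constant input, empty result, no head found)."""


@dataclass
class BinaryMask:
    """Boolean grid sharing a source volume's geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    source_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def shape(self):
        return self.data.shape

    @property
    def volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return float(self.data.sum()) * sx * sy * sz


def threshold_value(vol) -> float:
    """Otsu's between-class-variance-maximizing threshold (256 bins).

    Accepts a :class:`VoxelVolume` or a bare array; bins span the observed
    intensity range.  Raises :class:`ExtractionError` on constant input.
    """
    data = vol.data if isinstance(vol, VoxelVolume) else np.asarray(vol)
    if np.ptp(data) == 0:
        raise ExtractionError("cannot threshold a constant-intensity volume")
    return float(threshold_otsu(data, nbins=256))


def _fill_holes_slicewise(mask3d: np.ndarray) -> np.ndarray:
    """2D hole fill per axial slice (3D fill would fail on cavities open
    to the outside, e.g. nasal passages)."""
    out = np.empty_like(mask3d)
    for k in range(mask3d.shape[2]):
        out[:, :, k] = ndimage.binary_fill_holes(mask3d[:, :, k])
    return out


def mask_from_threshold(vol: VoxelVolume, threshold: float) -> BinaryMask:
    """Threshold + slice-wise hole fill, with no component selection.

    The minimal binarization used on calibration phantoms, where several
    disjoint rings coexist in one volume and each must survive.
    """
    binary = _fill_holes_slicewise(vol.data > threshold)
    return BinaryMask(binary, vol.spacing, vol.source_id)


def _border_fraction(component: np.ndarray) -> float:
    """Foreground fraction of the border voxels on five faces.

    The inferior face (slice 0 after canonicalization) is excluded: neck
    contact there is anatomically expected.
    """
    faces = [
        component[0, :, :],
        component[-1, :, :],
        component[:, 0, :],
        component[:, -1, :],
        component[:, :, -1],
    ]
    total = sum(f.size for f in faces)
    hit = sum(int(f.sum()) for f in faces)
    return hit / total


def extract_head_mask(
    vol: VoxelVolume,
    closing_radius: int = 2,
    border_fraction_max: float = 0.5,
    threshold: float | None = None,
) -> BinaryMask:
    """Extract the outer-skin head mask from a canonical volume.

    Pipeline: Otsu threshold (unless ``threshold`` is given) -> in-plane
    morphological closing (disk of ``closing_radius`` pixels) -> largest 3D
    connected component -> slice-wise hole fill.  The resulting boundary is
    the outer skin surface.

    Raises :class:`ExtractionError` for constant input, an empty result, or
    a component covering more than ``border_fraction_max`` of the volume
    border (background/foreground inversion — "no head found").
    """
    if threshold is None:
        threshold = threshold_value(vol)
    binary = vol.data > threshold
    if not binary.any():
        raise ExtractionError("thresholding produced an empty mask")

    if closing_radius > 0:
        footprint = disk(closing_radius)
        for k in range(binary.shape[2]):
            if binary[:, :, k].any():
                binary[:, :, k] = closing(binary[:, :, k], footprint)

    labels, n = ndimage.label(binary)
    if n == 0:
        raise ExtractionError("no foreground component after closing")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    component = labels == (int(np.argmax(sizes)) + 1)

    if _border_fraction(component) > border_fraction_max:
        raise ExtractionError(
            "no head found: largest component touches more than "
            f"{border_fraction_max:.0%} of the volume border"
        )

    filled = _fill_holes_slicewise(component)
    return BinaryMask(filled, vol.spacing, vol.source_id)
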