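"""Volumetric image I/O and canonical axial orientation.

The measurement pipeline operates on scanner-aligned axial stacks: after
canonicalization the third array axis runs inferior -> superior (RAS+), so
``data[:, :, k]`` is an axial slice.  Orientation handling is a pure axis
permutation/flip — no resampling is ever performed, because interpolation
would silently change measured perimeters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelVolume",
    "VolumeFormatError",
    "UnsupportedOrientationError",
    "read_volume",
    "write_volume",
    "to_canonical",
]

#: maximum deviation (degrees) of an acquisition axis from a grid axis
#: before the volume is rejected as oblique
OBLIQUE_TOLERANCE_DEG = 1.0

#: warn when in-plane pixels deviate from square by more than this fraction
ANISOTROPY_WARN_FRACTION = 0.05


class VolumeFormatError(ValueError):
    """The file or array does not describe a usable 3D volume."""


class UnsupportedOrientationError(ValueError):
    """The acquisition is oblique: axes are not within tolerance of a grid axis."""


@dataclass
class VoxelVolume:
    """A 3D intensity grid with physical voxel spacing.

    Parameters
    ----------
    data:
        3D scalar array, arbitrary intensity units.
    spacing:
        ``(sx, sy, sz)`` voxel size in mm along the three array axes.
    affine:
        Optional 4x4 voxel-to-world affine (NIfTI convention).  ``None``
        means orientation metadata is unavailable and the volume is assumed
        already canonical.
    orientation:
        Free tag; ``"canonical"`` after :func:`to_canonical`.
    source_id:
        Provenance string (file stem, subject id, ...).

    A voxel's physical center is ``index * spacing`` (0-based indices);
    masks and contours are defined on voxel centers.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None
    orientation: str = "unknown"
    source_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D volume, got {self.data.ndim} dimensions"
            )
        if any(n < 1 for n in self.data.shape):
            raise VolumeFormatError(f"degenerate volume shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or not all(
            np.isfinite(s) and s > 0 for s in self.spacing
        ):
            raise VolumeFormatError(f"invalid voxel spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def with_data(self, data: np.ndarray) -> "VoxelVolume":
        return replace(self, data=data)


def read_volume(path) -> VoxelVolume:
    """Read a NIfTI-1 volume (.nii / .nii.gz) with spacing from the header.

    Intensities are returned unmodified.  Raises
    :class:`FileNotFoundError` for a missing file, :class:`VolumeFormatError`
    for non-3D images or non-positive spacing.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3D image, found {data.ndim}D "
            f"(shape {data.shape})"
        )
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if not all(np.isfinite(z) and z > 0 for z in zooms):
        raise VolumeFormatError(f"{path}: non-positive voxel spacing {zooms}")
    return VoxelVolume(
        data=np.asarray(data, dtype=np.float64),
        spacing=zooms,
        affine=np.asarray(img.affine, dtype=float),
        orientation="as-stored",
        source_id=str(path),
    )


def write_volume(vol: VoxelVolume, path, dtype=None) -> None:
    """Write a volume as NIfTI-1, preserving spacing (and affine if present)."""
    if vol.affine is not None:
        affine = vol.affine
    else:
        affine = np.diag(list(vol.spacing) + [1.0])
    data = vol.data if dtype is None else vol.data.astype(dtype)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def _obliquity_deg(affine: np.ndarray) -> float:
    """Largest angle (degrees) between an image axis and its nearest grid axis."""
    rot = np.asarray(affine, dtype=float)[:3, :3]
    norms = np.linalg.norm(rot, axis=0)
    if np.any(norms == 0):
        raise VolumeFormatError("affine has a zero-length axis")
    cosines = np.max(np.abs(rot) / norms, axis=0)
    return float(np.degrees(np.arccos(np.clip(cosines, -1.0, 1.0))).max())


def to_canonical(vol: VoxelVolume) -> VoxelVolume:
    """Reorder/flip axes so axial slices lie along the third axis (RAS+).

    A pure permutation/flip of the stored grid; spacing is permuted
    consistently and intensities are untouched.  Volumes whose affine is
    oblique (any axis more than ``OBLIQUE_TOLERANCE_DEG`` off-grid) are
    rejected rather than resampled.  Volumes without an affine are assumed
    canonical, with a warning.
    """
    if vol.affine is None:
        if vol.orientation != "canonical":
            warnings.warn(
                "volume has no orientation metadata; assuming it is already "
                "canonical (axial along the third axis)",
                stacklevel=2,
            )
        return replace(vol, orientation="canonical")

    angle = _obliquity_deg(vol.affine)
    if angle > OBLIQUE_TOLERANCE_DEG:
        raise UnsupportedOrientationError(
            f"oblique acquisition: axis {angle:.2f} deg off the scanner grid "
            f"(tolerance {OBLIQUE_TOLERANCE_DEG} deg); resampling is not "
            "performed because it would alter measured perimeters"
        )

    ornt = nib.orientations.io_orientation(vol.affine)
    data = nib.orientations.apply_orientation(vol.data, ornt)
    # spacing follows its axis to the new position
    new_spacing = [0.0, 0.0, 0.0]
    for in_axis, (out_axis, _flip) in enumerate(ornt):
        new_spacing[int(out_axis)] = vol.spacing[in_axis]
    new_affine = vol.affine @ nib.orientations.inv_ornt_aff(ornt, vol.data.shape)

    sx, sy, _ = new_spacing
    if abs(sx / sy - 1.0) > ANISOTROPY_WARN_FRACTION:
        warnings.warn(
            f"in-plane pixels are anisotropic ({sx:g} x {sy:g} mm); "
            "computation proceeds using both spacings",
            stacklevel=2,
        )

    return VoxelVolume(
        data=data,
        spacing=tuple(new_spacing),
        affine=new_affine,
        orientation="canonical",
        source_id=vol.source_id,
        meta=dict(vol.meta),
    )
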