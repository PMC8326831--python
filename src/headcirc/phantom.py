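"""Synthetic calibration phantoms and head volumes with analytic ground truth.

The calibration protocol rasterizes stacks of annular rings whose outer
circumference is known exactly (C = D*pi), mirroring the 3D-printed ring
structures used to tune the instrument: rings 5 mm tall, each with a
different circumference spanning the mean head-circumference range of the
Nellhaus chart, imaged at clinical resolution (0.5 x 0.5 mm in-plane, 1 mm
slices, five slices per ring).

Rasterization emulates partial volume: each voxel's intensity is the
occupied fraction of its supersampled subcells times a nominal foreground
intensity, optionally degraded with Rician noise.  Every generated volume
carries a manifest with the analytic truth (ring circumferences, per-slice
outer perimeters) so downstream measurements can be scored against it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .volume import VoxelVolume

__all__ = [
    "RingSpec",
    "PhantomSpec",
    "HeadSpec",
    "RingTruth",
    "PhantomManifest",
    "HeadManifest",
    "GeometryError",
    "SizeError",
    "RING_CIRCUMFERENCES_CM",
    "nellhaus_ring_set",
    "rasterize_phantom",
    "rasterize_head",
    "export_stl",
    "ellipse_perimeter_mm",
]


class GeometryError(ValueError):
    """Invalid or overlapping solid geometry."""


class SizeError(ValueError):
    """The requested grid exceeds the voxel budget."""


#: Outer circumferences (cm) of the two calibration ring sets.  The younger
#: set spans mean head circumferences from birth to three years, the older
#: set from three to eighteen years.
RING_CIRCUMFERENCES_CM = {
    "0-3": (35.5, 39.3, 41.8, 43.4, 45.6, 46.5, 47.7, 48.4, 49.3),
    "3-18": (51.2, 52.8, 54.7, 55.3),
}


@dataclass(frozen=True)
class RingSpec:
    """Analytic geometry of one calibration ring (an annular solid).

    The *outer* boundary carries the certified circumference, since the
    physical rings were calipered across their outer diameter.
    """

    outer_diameter_mm: float
    height_mm: float = 5.0
    wall_mm: float = 3.0
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.outer_diameter_mm > 2 * self.wall_mm > 0):
            raise GeometryError(
                f"ring {self.label!r}: need outer_diameter > 2*wall > 0, got "
                f"D={self.outer_diameter_mm}, wall={self.wall_mm}"
            )
        if self.height_mm <= 0:
            raise GeometryError(f"ring {self.label!r}: non-positive height")

    @property
    def outer_radius_mm(self) -> float:
        return self.outer_diameter_mm / 2.0

    @property
    def inner_radius_mm(self) -> float:
        return self.outer_diameter_mm / 2.0 - self.wall_mm

    @property
    def circumference_cm(self) -> float:
        return math.pi * self.outer_diameter_mm / 10.0

    @property
    def z_interval_mm(self) -> tuple[float, float]:
        z0 = self.center_mm[2] - self.height_mm / 2.0
        return (z0, z0 + self.height_mm)


@dataclass
class PhantomSpec:
    """Rasterization recipe for a stack of rings."""

    rings: list  # list[RingSpec]
    spacing: tuple[float, float, float] = (0.5, 0.5, 1.0)
    supersample: int = 8
    noise_sigma: float = 0.0
    seed: int = 0
    foreground: float = 100.0
    margin_mm: float = 4.0
    extent_mm: tuple[float, float, float] | None = None  # used when rings == []
    voxel_budget: int = 500_000_000

    def __post_init__(self) -> None:
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"invalid spacing {self.spacing}")
        _check_disjoint(self.rings)


@dataclass
class HeadSpec:
    """Layered quasi-ellipsoidal head: brain core plus a scalp shell.

    The outer surface at height z (measured from the head center, half-height
    ``c``) is an ellipse with semi-axes ``(a*s, b*s)`` where
    ``s = (1 - (z/c)^2)^(taper/2)``.  ``taper = 1`` gives an ellipsoid,
    ``taper = 0`` an elliptic cylinder.  The shell adds ``shell_mm`` to every
    semi-axis, so each cross-section's outer boundary stays an exact ellipse
    with analytically integrable perimeter.
    """

    semi_axes_mm: tuple[float, float, float] = (80.0, 70.0, 75.0)
    shell_mm: float = 6.0
    brain_intensity: float = 100.0
    scalp_intensity: float = 85.0
    taper: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0
    supersample: int = 8
    margin_mm: float = 4.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.semi_axes_mm):
            raise ValueError(f"degenerate semi-axes {self.semi_axes_mm}")
        if self.shell_mm < 0:
            raise ValueError("shell thickness must be >= 0")
        if self.taper < 0:
            raise ValueError("taper must be >= 0")

    @property
    def outer_semi_axes_mm(self) -> tuple[float, float, float]:
        a, b, c = self.semi_axes_mm
        t = self.shell_mm
        return (a + t, b + t, c + t)


@dataclass(frozen=True)
class RingTruth:
    """Analytic ground truth for one rasterized ring (grid frame)."""

    label: str
    outer_diameter_mm: float
    circumference_cm: float
    center_mm: tuple[float, float, float]
    z_interval_mm: tuple[float, float]


@dataclass
class PhantomManifest:
    """Ground-truth sidecar of a rasterized ring phantom."""

    rings: list  # list[RingTruth]
    spacing: tuple[float, float, float]
    foreground: float
    group: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "group": self.group,
                "spacing_mm": list(self.spacing),
                "foreground": self.foreground,
                "rings": [
                    {
                        "label": r.label,
                        "outer_diameter_mm": r.outer_diameter_mm,
                        "circumference_cm": r.circumference_cm,
                        "center_mm": list(r.center_mm),
                        "z_interval_mm": list(r.z_interval_mm),
                    }
                    for r in self.rings
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PhantomManifest":
        obj = json.loads(text)
        rings = [
            RingTruth(
                label=r["label"],
                outer_diameter_mm=r["outer_diameter_mm"],
                circumference_cm=r["circumference_cm"],
                center_mm=tuple(r["center_mm"]),
                z_interval_mm=tuple(r["z_interval_mm"]),
            )
            for r in obj["rings"]
        ]
        return cls(
            rings=rings,
            spacing=tuple(obj["spacing_mm"]),
            foreground=obj["foreground"],
            group=obj.get("group"),
        )


@dataclass
class HeadManifest:
    """Per-slice analytic truth for a rasterized head volume."""

    slice_perimeter_mm: np.ndarray  # outer-contour perimeter per axial slice (nan if empty)
    equator_index: int
    max_perimeter_mm: float
    outer_semi_axes_mm: tuple[float, float, float]
    center_mm: tuple[float, float, float]
    spacing: tuple[float, float, float]


def ellipse_perimeter_mm(a_mm: float, b_mm: float, epsrel: float = 1e-9) -> float:
    """Perimeter of an ellipse by adaptive arc-length quadrature.

    There is no elementary closed form; the integrand is
    sqrt(a^2 sin^2 t + b^2 cos^2 t) over a quarter period, times four.
    """
    if a_mm <= 0 or b_mm <= 0:
        raise ValueError("semi-axes must be positive")
    val, _err = quad(
        lambda t: math.hypot(a_mm * math.sin(t), b_mm * math.cos(t)),
        0.0,
        math.pi / 2.0,
        epsrel=epsrel,
    )
    return 4.0 * val


def nellhaus_ring_set(
    group: str,
    wall_mm: float = 3.0,
    height_mm: float = 5.0,
    gap_mm: float = 2.0,
    z_start_mm: float = 2.5,
    circumferences_cm=None,
) -> list:
    """Build the ring set whose outer circumferences track the growth chart.

    ``group`` is ``"0-3"`` (nine rings, birth to three years) or ``"3-18"``
    (four rings).  Outer diameter is C/pi; rings are stacked along z with a
    two-slice gap so slice-to-ring assignment is unambiguous.  The default
    ``z_start_mm`` aligns ring faces to a 1 mm slice grid (voxel centers at
    integer mm), so each 5 mm ring occupies exactly five full slices — the
    acquisition geometry the calibration protocol prescribes.
    """
    if circumferences_cm is None:
        try:
            circumferences_cm = RING_CIRCUMFERENCES_CM[group]
        except KeyError:
            raise ValueError(
                f"unknown ring group {group!r}; expected one of "
                f"{sorted(RING_CIRCUMFERENCES_CM)}"
            ) from None
    rings = []
    pitch = height_mm + gap_mm
    for i, c_cm in enumerate(circumferences_cm):
        z0 = z_start_mm + i * pitch
        rings.append(
            RingSpec(
                outer_diameter_mm=c_cm * 10.0 / math.pi,
                height_mm=height_mm,
                wall_mm=wall_mm,
                center_mm=(0.0, 0.0, z0 + height_mm / 2.0),
                label=f"{group}/ring{i + 1}",
            )
        )
    return rings


def _check_disjoint(rings) -> None:
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            a, b = rings[i], rings[j]
            za, zb = a.z_interval_mm, b.z_interval_mm
            z_overlap = za[0] < zb[1] and zb[0] < za[1]
            d = math.hypot(
                a.center_mm[0] - b.center_mm[0], a.center_mm[1] - b.center_mm[1]
            )
            if z_overlap and d < a.outer_radius_mm + b.outer_radius_mm:
                raise GeometryError(
                    f"rings {a.label!r} and {b.label!r} overlap in physical space"
                )


def _ellipse_coverage(
    n0: int,
    n1: int,
    s0: float,
    s1: float,
    c0: float,
    c1: float,
    a: float,
    b: float,
    supersample: int,
) -> np.ndarray:
    """Pixel coverage fractions of the filled ellipse ((x-c0)/a)^2+((y-c1)/b)^2<=1.

    Pixels entirely inside/outside (certified by a gradient bound on the
    normalized radius) are set to 1/0 directly; only the boundary band is
    supersampled with ``supersample**2`` subcell centers, so the result is
    identical to full supersampling at a fraction of the cost.
    """
    x = np.arange(n0) * s0
    y = np.arange(n1) * s1
    rho = np.sqrt(
        ((x[:, None] - c0) / a) ** 2 + ((y[None, :] - c1) / b) ** 2
    )
    # |d rho| over one pixel is bounded by 0.5*(s0/a + s1/b)
    delta = 0.5 * (s0 / a + s1 / b)
    cov = (rho <= 1.0 - delta).astype(np.float64)
    band = np.abs(rho - 1.0) < delta
    if np.any(band):
        ss = supersample
        off0 = ((np.arange(ss) + 0.5) / ss - 0.5) * s0
        off1 = ((np.arange(ss) + 0.5) / ss - 0.5) * s1
        bi, bj = np.nonzero(band)
        subx = x[bi][:, None, None] + off0[None, :, None]
        suby = y[bj][:, None, None] + off1[None, None, :]
        inside = ((subx - c0) / a) ** 2 + ((suby - c1) / b) ** 2 <= 1.0
        cov[bi, bj] = inside.mean(axis=(1, 2))
    return cov


def _apply_rician(data: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    if sigma <= 0:
        return data
    rng = np.random.default_rng(seed)
    real = data + rng.normal(0.0, sigma, data.shape)
    imag = rng.normal(0.0, sigma, data.shape)
    return np.hypot(real, imag)


def rasterize_phantom(spec: PhantomSpec) -> VoxelVolume:
    """Rasterize a ring stack into a partial-volume intensity grid.

    Each voxel's value is ``foreground`` times the occupied fraction of its
    ``supersample``-per-axis subcells (the in-plane annulus coverage and the
    z overlap factorize exactly, so they are computed separately).  The
    returned volume carries ``meta["manifest"]``: a :class:`PhantomManifest`
    with each ring's analytic circumference and z extent, in the grid frame
    where a voxel center sits at ``index * spacing``.
    """
    sx, sy, sz = spec.spacing
    if not spec.rings:
        if spec.extent_mm is None:
            raise GeometryError(
                "empty ring list: provide extent_mm for an empty phantom"
            )
        shape = tuple(int(math.ceil(e / s)) + 1 for e, s in zip(spec.extent_mm, spec.spacing))
        _check_budget(shape, spec.voxel_budget)
        vol = VoxelVolume(
            data=_apply_rician(np.zeros(shape), spec.noise_sigma, spec.seed),
            spacing=spec.spacing,
            orientation="canonical",
            source_id="phantom:empty",
        )
        vol.meta["manifest"] = PhantomManifest(
            rings=[], spacing=spec.spacing, foreground=spec.foreground
        )
        return vol

    m = spec.margin_mm
    x_lo = min(r.center_mm[0] - r.outer_radius_mm for r in spec.rings) - m
    x_hi = max(r.center_mm[0] + r.outer_radius_mm for r in spec.rings) + m
    y_lo = min(r.center_mm[1] - r.outer_radius_mm for r in spec.rings) - m
    y_hi = max(r.center_mm[1] + r.outer_radius_mm for r in spec.rings) + m
    z_lo = 0.0
    z_hi = max(r.z_interval_mm[1] for r in spec.rings) + m

    nx = int(math.ceil((x_hi - x_lo) / sx)) + 1
    ny = int(math.ceil((y_hi - y_lo) / sy)) + 1
    nz = int(math.ceil((z_hi - z_lo) / sz)) + 1
    _check_budget((nx, ny, nz), spec.voxel_budget)

    data = np.zeros((nx, ny, nz), dtype=np.float64)
    ss = spec.supersample
    zoff = ((np.arange(ss) + 0.5) / ss - 0.5) * sz
    z_centers = np.arange(nz) * sz

    truths = []
    for ring in spec.rings:
        cx = ring.center_mm[0] - x_lo
        cy = ring.center_mm[1] - y_lo
        cov_out = _ellipse_coverage(
            nx, ny, sx, sy, cx, cy, ring.outer_radius_mm, ring.outer_radius_mm, ss
        )
        cov_in = _ellipse_coverage(
            nx, ny, sx, sy, cx, cy, ring.inner_radius_mm, ring.inner_radius_mm, ss
        )
        cov2d = cov_out - cov_in
        z0, z1 = ring.z_interval_mm
        zsub = z_centers[:, None] + zoff[None, :]
        frac_z = np.mean((zsub >= z0) & (zsub <= z1), axis=1)
        for k in np.nonzero(frac_z > 0)[0]:
            data[:, :, k] += spec.foreground * cov2d * frac_z[k]
        truths.append(
            RingTruth(
                label=ring.label,
                outer_diameter_mm=ring.outer_diameter_mm,
                circumference_cm=ring.circumference_cm,
                center_mm=(cx, cy, ring.center_mm[2]),
                z_interval_mm=(z0, z1),
            )
        )

    data = _apply_rician(data, spec.noise_sigma, spec.seed)
    vol = VoxelVolume(
        data=data,
        spacing=spec.spacing,
        orientation="canonical",
        source_id=f"phantom:{len(spec.rings)}rings",
    )
    vol.meta["manifest"] = PhantomManifest(
        rings=truths, spacing=spec.spacing, foreground=spec.foreground
    )
    return vol


def _check_budget(shape, budget) -> None:
    n = int(np.prod([int(s) for s in shape]))
    if n > budget:
        raise SizeError(f"grid {shape} has {n} voxels, exceeding budget {budget}")


def _section_scale(u: float, taper: float) -> float:
    """Cross-section scale factor at normalized height u = z/c (0 outside)."""
    if abs(u) >= 1.0:
        return 0.0
    return (1.0 - u * u) ** (taper / 2.0)


def rasterize_head(spec: HeadSpec, spacing=(0.5, 0.5, 1.0)) -> VoxelVolume:
    """Rasterize a layered synthetic head with per-slice analytic truth.

    The manifest (``meta["manifest"]``, a :class:`HeadManifest`) records, for
    every axial slice, the true outer-contour perimeter obtained by numeric
    arc-length quadrature of the analytic elliptical cross-section at the
    slice-center height.
    """
    sx, sy, sz = (float(s) for s in spacing)
    if min(sx, sy, sz) <= 0:
        raise ValueError(f"invalid spacing {spacing}")
    ao, bo, co = spec.outer_semi_axes_mm
    ai, bi_, ci = spec.semi_axes_mm
    m = spec.margin_mm
    nx = int(math.ceil(2 * (ao + m) / sx)) + 1
    ny = int(math.ceil(2 * (bo + m) / sy)) + 1
    nz = int(math.ceil(2 * (co + m) / sz)) + 1
    cx, cy, cz = (nx - 1) / 2.0 * sx, (ny - 1) / 2.0 * sy, (nz - 1) / 2.0 * sz

    ss = spec.supersample
    zoff = ((np.arange(ss) + 0.5) / ss - 0.5) * sz
    data = np.zeros((nx, ny, nz), dtype=np.float64)
    scalp = spec.scalp_intensity
    brain = spec.brain_intensity

    for k in range(nz):
        zc = k * sz
        acc = np.zeros((nx, ny))
        for dz in zoff:
            z = zc + dz
            s_out = _section_scale((z - cz) / co, spec.taper)
            if s_out > 0:
                cov = _ellipse_coverage(
                    nx, ny, sx, sy, cx, cy, ao * s_out, bo * s_out, ss
                )
                acc += scalp * cov
            s_in = _section_scale((z - cz) / ci, spec.taper)
            if s_in > 0:
                cov = _ellipse_coverage(
                    nx, ny, sx, sy, cx, cy, ai * s_in, bi_ * s_in, ss
                )
                acc += (brain - scalp) * cov
        data[:, :, k] = acc / ss

    data = _apply_rician(data, spec.noise_sigma, spec.seed)

    perims = np.full(nz, np.nan)
    for k in range(nz):
        s_out = _section_scale((k * sz - cz) / co, spec.taper)
        if s_out > 0:
            perims[k] = ellipse_perimeter_mm(ao * s_out, bo * s_out, epsrel=1e-6)
    equator = int(np.nanargmax(perims))

    vol = VoxelVolume(
        data=data,
        spacing=(sx, sy, sz),
        orientation="canonical",
        source_id="synthetic-head",
    )
    vol.meta["manifest"] = HeadManifest(
        slice_perimeter_mm=perims,
        equator_index=equator,
        max_perimeter_mm=float(np.nanmax(perims)),
        outer_semi_axes_mm=(ao, bo, co),
        center_mm=(cx, cy, cz),
        spacing=(sx, sy, sz),
    )
    return vol


def export_stl(rings, path, ascii_format: bool = False, sections: int = 512):
    """Write the union of annular solids as a watertight STL mesh.

    Each ring becomes an extruded annulus with ``sections`` angular facets;
    the rings are disjoint, so their union is the concatenation of watertight
    components.  Returns the mesh.
    """
    import trimesh

    if not rings:
        raise ValueError("no rings to export")
    _check_disjoint(rings)
    meshes = []
    for ring in rings:
        mesh = trimesh.creation.annulus(
            r_min=ring.inner_radius_mm,
            r_max=ring.outer_radius_mm,
            height=ring.height_mm,
            sections=sections,
        )
        mesh.apply_translation(ring.center_mm)
        meshes.append(mesh)
    combined = trimesh.util.concatenate(meshes)
    combined.export(str(path), file_type="stl_ascii" if ascii_format else "stl")
    return combined
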