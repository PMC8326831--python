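"""Per-slice area, boundary tracing, and digital perimeter estimation.

The head circumference is the perimeter of the maximum-area axial slice of
the head mask.  Measuring a digital boundary is biased by construction —
counting chain moves overestimates a circle by up to 4/pi — so four
estimators with different bias behavior are provided:

``pixel_count``
    City-block (4-connected) chain length, ``Ne + 2*Nd``.  The classic
    uncorrected digital boundary length; overestimates a large digital
    circle by a factor approaching 4/pi (~1.273).
``freeman``
    Chain length with diagonal moves weighted sqrt(2): ``Ne + sqrt(2)*Nd``.
    Overestimates smooth boundaries by ~5%.
``corner_corrected`` (default)
    Vossepoel-Smeulders weights ``0.980*Ne + 1.406*Nd - 0.091*Nc`` where
    ``Nc`` counts direction changes; bias well under 1% on smooth convex
    shapes.
``subpixel``
    Polygon arc length of the 0.5-isolevel contour of the lightly smoothed
    mask (marching squares with linear interpolation).  Handles anisotropic
    pixels natively; error ~0.2% on large digitized circles.

Residual estimator bias is absorbed downstream by the phantom-derived
correction factors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter
from skimage.measure import find_contours

from .mask import BinaryMask

__all__ = [
    "PERIMETER_METHODS",
    "ChainContour",
    "SliceMeasurement",
    "slice_area",
    "trace_boundary",
    "perimeter_estimate",
    "find_mhc_slice",
    "all_slice_profile",
    "profile_to_csv",
]

PERIMETER_METHODS = ("pixel_count", "freeman", "corner_corrected", "subpixel")

#: Vossepoel-Smeulders chain-length weights (even moves, diagonal moves,
#: corner count)
_VS_EVEN, _VS_DIAG, _VS_CORNER = 0.980, 1.406, -0.091

#: Gaussian pre-smoothing (pixels) for the subpixel 0.5-isolevel contour;
#: removes staircase vertices so the interpolated polygon tracks the true
#: boundary to ~0.2% on circles with r >= 50 px
_SUBPIXEL_SIGMA = 1.5

# Freeman directions in (row, col) array coordinates; code 0 = +col, odd
# codes are diagonals, numbering counter-clockwise when rows point up.
_DIRS = np.array(
    [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)],
    dtype=int,
)
# direction from the new pixel back to the last background neighbor scanned
# (Moore tracing backtrack): vector dirs[d-1] - dirs[d] is always itself a
# neighbor step; precompute its code.
_VEC2CODE = {tuple(v): c for c, v in enumerate(_DIRS)}
_BACKTRACK = np.array(
    [_VEC2CODE[tuple(_DIRS[(d - 1) % 8] - _DIRS[d])] for d in range(8)], dtype=int
)


@dataclass
class ChainContour:
    """Closed Freeman chain of a region's outer boundary.

    ``codes`` are moves in {0..7} starting from ``start`` (the
    lexicographically smallest foreground pixel); even codes step one pixel
    along an axis, odd codes step diagonally.  ``degenerate`` flags a
    single-pixel region, whose chain is empty.  The source slice is kept so
    grid-based estimators (subpixel) can reuse it.
    """

    codes: np.ndarray
    start: tuple[int, int]
    degenerate: bool
    mask_slice: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def n_even(self) -> int:
        return int(np.sum(self.codes % 2 == 0)) if len(self.codes) else 0

    @property
    def n_diagonal(self) -> int:
        return int(np.sum(self.codes % 2 == 1)) if len(self.codes) else 0

    @property
    def n_corners(self) -> int:
        """Number of direction changes along the closed chain."""
        if len(self.codes) < 2:
            return 0
        return int(np.sum(self.codes != np.roll(self.codes, 1)))

    def pixels(self) -> np.ndarray:
        """(n+1, 2) array of visited pixel coordinates, closed."""
        steps = _DIRS[self.codes] if len(self.codes) else np.zeros((0, 2), int)
        return np.vstack([self.start, self.start + np.cumsum(steps, axis=0)])


@dataclass
class SliceMeasurement:
    """Area and perimeter of one axial slice."""

    slice_index: int
    area_mm2: float
    perimeter_mm: dict
    method: str
    n_boundary_moves: tuple[int, int, int]  # (even, diagonal, corner) counts
    z_mm: float = 0.0
    z_uncertainty_mm: float = 0.0
    degenerate: bool = False

    @property
    def perimeter_cm(self) -> float:
        return self.perimeter_mm[self.method] / 10.0


def slice_area(mask_slice: np.ndarray, spacing) -> float:
    """Foreground pixel count times the in-plane pixel area (mm^2)."""
    sx, sy = spacing[0], spacing[1]
    return float(np.count_nonzero(mask_slice)) * sx * sy


def trace_boundary(mask_slice: np.ndarray) -> ChainContour:
    """Moore-neighbor trace of the outer contour as a closed Freeman chain.

    The slice must contain exactly one 8-connected foreground component.
    The trace starts at the lexicographically smallest foreground pixel and
    stops on Jacob's criterion (start pixel re-entered with the same
    backtrack state), guaranteeing a closed chain.  Orientation is
    normalized counter-clockwise (positive shoelace area with rows as -y).
    A single-pixel region yields an empty chain flagged degenerate.
    """
    mask_slice = np.asarray(mask_slice, dtype=bool)
    if not mask_slice.any():
        raise ValueError("cannot trace an empty slice")
    _, n = ndimage.label(mask_slice, structure=np.ones((3, 3), dtype=int))
    if n != 1:
        raise ValueError(
            f"slice has {n} foreground components; boundary tracing requires "
            "exactly one (run mask extraction first)"
        )

    fg = np.argwhere(mask_slice)
    order = np.lexsort((fg[:, 1], fg[:, 0]))
    start = tuple(int(v) for v in fg[order[0]])
    if len(fg) == 1:
        return ChainContour(
            codes=np.zeros(0, dtype=int),
            start=start,
            degenerate=True,
            mask_slice=mask_slice,
        )

    nrow, ncol = mask_slice.shape

    def is_fg(r: int, c: int) -> bool:
        return 0 <= r < nrow and 0 <= c < ncol and mask_slice[r, c]

    codes: list[int] = []
    cur = start
    b_dir = 4  # backtrack points west of the start pixel (background there)
    limit = 4 * mask_slice.size
    while True:
        nxt = None
        for k in range(1, 9):
            d = (b_dir + k) % 8
            nr, nc = cur[0] + _DIRS[d][0], cur[1] + _DIRS[d][1]
            if is_fg(nr, nc):
                nxt = (d, (nr, nc))
                break
        if nxt is None:  # unreachable for a 2+ pixel connected component
            break
        d, cur_next = nxt
        # closure: about to repeat the first move from the start pixel; the
        # trace is deterministic in (pixel, backtrack) state, so repeating
        # the first move means the whole cycle would repeat
        if codes and cur == start and d == codes[0]:
            break
        codes.append(d)
        cur = cur_next
        b_dir = int(_BACKTRACK[d])
        if len(codes) > limit:
            raise RuntimeError("boundary trace failed to close")

    chain = ChainContour(
        codes=np.asarray(codes, dtype=int),
        start=start,
        degenerate=False,
        mask_slice=mask_slice,
    )
    # enforce counter-clockwise orientation (shoelace in (col, -row) coords)
    px = chain.pixels()
    x, y = px[:, 1].astype(float), -px[:, 0].astype(float)
    signed_area = 0.5 * np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])
    if signed_area < 0:
        # reversing a closed chain keeps the start pixel (path ends there)
        chain.codes = (chain.codes[::-1] + 4) % 8
    return chain


def _step_mm(spacing) -> float:
    """Unit chain step in mm; geometric mean for (mildly) anisotropic pixels."""
    sx, sy = float(spacing[0]), float(spacing[1])
    if abs(sx / sy - 1.0) > 0.05:
        warnings.warn(
            f"chain-based perimeter on anisotropic pixels ({sx:g} x {sy:g} mm): "
            "using the geometric-mean spacing; prefer the subpixel method",
            stacklevel=3,
        )
    return math.sqrt(sx * sy)


def _subpixel_length_mm(mask_slice: np.ndarray, spacing) -> float:
    """Arc length of the 0.5-isolevel contour of the smoothed mask (mm)."""
    sx, sy = float(spacing[0]), float(spacing[1])
    pad = int(math.ceil(4 * _SUBPIXEL_SIGMA)) + 1
    f = np.pad(mask_slice.astype(np.float64), pad)
    f = gaussian_filter(f, _SUBPIXEL_SIGMA)
    contours = find_contours(f, 0.5)
    if not contours:
        raise ValueError("no 0.5-isolevel contour found")
    longest = max(contours, key=lambda c: len(c))
    dr = np.diff(longest[:, 0]) * sx  # rows advance along the first axis
    dc = np.diff(longest[:, 1]) * sy
    return float(np.sum(np.hypot(dr, dc)))


def perimeter_estimate(chain: ChainContour, spacing, method: str = "corner_corrected") -> float:
    """Estimate the boundary length in mm from a closed chain.

    ``spacing`` is the in-plane ``(sx, sy)`` (a 3-tuple is accepted; the
    third component is ignored).  See the module docstring for the four
    methods.  A degenerate single-pixel region reports ``4 * pixel side``.
    """
    if method not in PERIMETER_METHODS:
        raise ValueError(
            f"unknown perimeter method {method!r}; expected one of {PERIMETER_METHODS}"
        )
    if chain.degenerate:
        return 4.0 * _step_mm(spacing)
    if method == "subpixel":
        return _subpixel_length_mm(chain.mask_slice, spacing)
    step = _step_mm(spacing)
    ne, nd = chain.n_even, chain.n_diagonal
    if method == "pixel_count":
        return step * (ne + 2 * nd)
    if method == "freeman":
        return step * (ne + math.sqrt(2.0) * nd)
    # corner_corrected
    return step * (_VS_EVEN * ne + _VS_DIAG * nd + _VS_CORNER * chain.n_corners)


def _measure_slice(
    mask_slice: np.ndarray,
    spacing,
    k: int,
    method: str,
    all_methods: bool = False,
) -> SliceMeasurement:
    chain = trace_boundary(mask_slice)
    methods = PERIMETER_METHODS if all_methods else (method,)
    perim = {m: perimeter_estimate(chain, spacing, m) for m in methods}
    sz = float(spacing[2]) if len(spacing) > 2 else 0.0
    return SliceMeasurement(
        slice_index=k,
        area_mm2=slice_area(mask_slice, spacing),
        perimeter_mm=perim,
        method=method,
        n_boundary_moves=(chain.n_even, chain.n_diagonal, chain.n_corners),
        z_mm=k * sz,
        z_uncertainty_mm=sz / 2.0,
        degenerate=chain.degenerate,
    )


def find_mhc_slice(
    mask: BinaryMask, method: str = "corner_corrected", all_methods: bool = False
) -> SliceMeasurement:
    """Select the maximum-area axial slice and measure its perimeter.

    Areas are computed for every slice; the slice with maximal area wins
    (ties break to the smallest index, i.e. the more inferior slice).  The
    z localization uncertainty is half the slice thickness: the true
    maximum can lie anywhere within the winning slice's extent.
    """
    counts = mask.data.sum(axis=(0, 1))
    if counts.max() == 0:
        raise ValueError("empty mask: no foreground in any slice")
    k = int(np.argmax(counts))  # argmax returns the first (lowest) maximum
    return _measure_slice(mask.data[:, :, k], mask.spacing, k, method, all_methods)


def all_slice_profile(
    mask: BinaryMask, method: str = "corner_corrected"
) -> list[SliceMeasurement]:
    """Area and perimeter of every occupied slice, in slice order.

    Enables whole-skull shape analysis beyond the single MHC value.
    """
    counts = mask.data.sum(axis=(0, 1))
    if counts.max() == 0:
        raise ValueError("empty mask: no foreground in any slice")
    return [
        _measure_slice(mask.data[:, :, k], mask.spacing, int(k), method)
        for k in np.nonzero(counts)[0]
    ]


def profile_to_csv(profile, path) -> None:
    """Write a slice profile as CSV (slice_index, z_mm, area_mm2, perimeter_mm, method)."""
    import pandas as pd

    rows = [
        {
            "slice_index": s.slice_index,
            "z_mm": s.z_mm,
            "area_mm2": s.area_mm2,
            "perimeter_mm": s.perimeter_mm[s.method],
            "method": s.method,
        }
        for s in profile
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
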