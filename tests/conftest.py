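"""Shared fixtures: expensive synthetic volumes built once per session."""

import numpy as np
import pytest

import headcirc as hc
from headcirc.phantom import HeadSpec, PhantomSpec


def digitized_disk(radius_px: int, pad: int = 4) -> np.ndarray:
    """Boolean disk: pixels whose centers fall inside the circle."""
    n = 2 * (radius_px + pad) + 1
    c = radius_px + pad
    yy, xx = np.mgrid[0:n, 0:n]
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius_px**2


def digitized_ellipse(a_px: float, b_px: float, pad: int = 4) -> np.ndarray:
    n0 = 2 * (int(a_px) + pad) + 1
    n1 = 2 * (int(b_px) + pad) + 1
    c0, c1 = (n0 - 1) / 2.0, (n1 - 1) / 2.0
    ii, jj = np.mgrid[0:n0, 0:n1]
    return ((ii - c0) / a_px) ** 2 + ((jj - c1) / b_px) ** 2 <= 1.0


@pytest.fixture(scope="session")
def phantom_0_3():
    """Noiseless nine-ring calibration phantom at clinical resolution."""
    spec = PhantomSpec(rings=hc.nellhaus_ring_set("0-3"), spacing=(0.5, 0.5, 1.0))
    return hc.rasterize_phantom(spec)


@pytest.fixture(scope="session")
def sphere_volume():
    """Noiseless rasterized sphere, R = 80 mm, at (0.5, 0.5, 1.0) mm."""
    return hc.rasterize_head(
        HeadSpec(semi_axes_mm=(80.0, 80.0, 80.0), shell_mm=0.0, taper=1.0),
        spacing=(0.5, 0.5, 1.0),
    )


@pytest.fixture(scope="session")
def small_head_volume():
    """Small layered head for fast end-to-end tests."""
    return hc.rasterize_head(
        HeadSpec(semi_axes_mm=(40.0, 35.0, 38.0), shell_mm=4.0),
        spacing=(1.0, 1.0, 2.0),
    )
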