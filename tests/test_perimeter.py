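"""Boundary tracing, perimeter estimators, and max-area slice selection."""

import math

import numpy as np
import pytest

from headcirc.mask import BinaryMask
from headcirc.perimeter import (
    PERIMETER_METHODS,
    all_slice_profile,
    find_mhc_slice,
    perimeter_estimate,
    slice_area,
    trace_boundary,
)

from conftest import digitized_disk, digitized_ellipse


class TestSliceArea:
    def test_empty_slice_is_zero(self):
        assert slice_area(np.zeros((5, 5), bool), (0.5, 0.5)) == 0.0

    def test_full_slice_exact_count(self):
        assert slice_area(np.ones((100, 100), bool), (0.5, 0.5)) == 2500.0

    def test_digitized_disk_area_near_analytic(self):
        m = digitized_disk(100)
        assert slice_area(m, (0.5, 0.5)) == pytest.approx(
            math.pi * 50.0**2, rel=0.01
        )


class TestTraceBoundary:
    def test_single_pixel_is_degenerate(self):
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        chain = trace_boundary(m)
        assert chain.degenerate
        assert len(chain) == 0

    def test_3x3_square_has_eight_even_moves(self):
        m = np.zeros((5, 5), bool)
        m[1:4, 1:4] = True
        chain = trace_boundary(m)
        assert len(chain) == 8
        assert chain.n_even == 8
        assert chain.n_diagonal == 0

    def test_chain_is_closed(self):
        m = digitized_disk(20)
        px = trace_boundary(m).pixels()
        assert tuple(px[0]) == tuple(px[-1])

    def test_rotation_by_180_preserves_move_counts(self):
        rng = np.random.default_rng(5)
        blob = digitized_ellipse(17.3, 9.1)
        rot = blob[::-1, ::-1].copy()
        c1, c2 = trace_boundary(blob), trace_boundary(rot)
        assert len(c1) == len(c2)
        assert (c1.n_even, c1.n_diagonal) == (c2.n_even, c2.n_diagonal)

    def test_multiple_components_rejected(self):
        m = np.zeros((9, 9), bool)
        m[1:3, 1:3] = True
        m[6:8, 6:8] = True
        with pytest.raises(ValueError, match="components"):
            trace_boundary(m)

    def test_empty_slice_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            trace_boundary(np.zeros((4, 4), bool))


class TestPerimeterEstimate:
    def test_axis_aligned_square_freeman_exact(self):
        m = np.zeros((44, 44), bool)
        m[2:42, 2:42] = True  # 40 px side at 1 mm
        chain = trace_boundary(m)
        assert perimeter_estimate(chain, (1.0, 1.0), "freeman") == pytest.approx(
            4 * (40 - 1), abs=1e-9
        )  # chain path connects the 40 boundary pixel centers per side

    def test_diamond_freeman_matches_diagonal_length(self):
        # 45-degree square: |x| + |y| <= s
        s = 30
        n = 2 * s + 5
        c = n // 2
        ii, jj = np.mgrid[0:n, 0:n]
        m = np.abs(ii - c) + np.abs(jj - c) <= s
        chain = trace_boundary(m)
        est = perimeter_estimate(chain, (1.0, 1.0), "freeman")
        analytic = 4 * s * math.sqrt(2.0)
        assert est == pytest.approx(analytic, abs=4 * math.sqrt(2.0))

    @pytest.mark.parametrize("radius", [100, 200, 400])
    def test_corner_corrected_within_1pct_on_circles(self, radius):
        chain = trace_boundary(digitized_disk(radius))
        est = perimeter_estimate(chain, (1.0, 1.0), "corner_corrected")
        assert est == pytest.approx(2 * math.pi * radius, rel=0.01)

    @pytest.mark.parametrize("radius", [100, 200, 400])
    def test_subpixel_within_half_pct_on_circles(self, radius):
        chain = trace_boundary(digitized_disk(radius))
        est = perimeter_estimate(chain, (1.0, 1.0), "subpixel")
        assert est == pytest.approx(2 * math.pi * radius, rel=0.005)

    @pytest.mark.parametrize("radius", [100, 200, 400])
    def test_pixel_count_approaches_four_over_pi(self, radius):
        chain = trace_boundary(digitized_disk(radius))
        ratio = perimeter_estimate(chain, (1.0, 1.0), "pixel_count") / (
            2 * math.pi * radius
        )
        assert 1.15 <= ratio <= 4 / math.pi + 0.01

    def test_estimator_ordering_on_convex_shapes(self):
        for mask in (digitized_disk(150), digitized_ellipse(120.0, 80.0)):
            chain = trace_boundary(mask)
            pc = perimeter_estimate(chain, (1.0, 1.0), "pixel_count")
            fr = perimeter_estimate(chain, (1.0, 1.0), "freeman")
            cc = perimeter_estimate(chain, (1.0, 1.0), "corner_corrected")
            assert pc >= fr >= cc

    @pytest.mark.parametrize("axes", [(100.0, 50.0), (80.0, 60.0), (60.0, 50.0)])
    def test_subpixel_and_corner_corrected_agree_on_ellipses(self, axes):
        chain = trace_boundary(digitized_ellipse(*axes))
        cc = perimeter_estimate(chain, (1.0, 1.0), "corner_corrected")
        sp = perimeter_estimate(chain, (1.0, 1.0), "subpixel")
        assert sp == pytest.approx(cc, rel=0.01)

    def test_isoperimetric_bound_holds(self):
        for mask in (
            digitized_disk(60),
            digitized_ellipse(70.0, 40.0),
            digitized_disk(150),
        ):
            area = slice_area(mask, (1.0, 1.0))
            chain = trace_boundary(mask)
            for method in PERIMETER_METHODS:
                p = perimeter_estimate(chain, (1.0, 1.0), method)
                assert 4 * math.pi * area <= p * p * 1.02

    def test_mm_result_invariant_under_spacing_radius_rescale(self):
        # same physical circle digitized at two resolutions
        p_fine = perimeter_estimate(
            trace_boundary(digitized_disk(200)), (0.5, 0.5), "corner_corrected"
        )
        p_coarse = perimeter_estimate(
            trace_boundary(digitized_disk(100)), (1.0, 1.0), "corner_corrected"
        )
        assert p_fine == pytest.approx(p_coarse, rel=0.01)

    def test_degenerate_pixel_reports_four_sides(self):
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        chain = trace_boundary(m)
        assert perimeter_estimate(chain, (0.5, 0.5), "pixel_count") == pytest.approx(2.0)

    def test_unknown_method_rejected(self):
        chain = trace_boundary(digitized_disk(10))
        with pytest.raises(ValueError, match="unknown perimeter method"):
            perimeter_estimate(chain, (1.0, 1.0), "magic")

    def test_anisotropic_spacing_warns_for_chain_methods(self):
        chain = trace_boundary(digitized_disk(30))
        with pytest.warns(UserWarning, match="anisotropic"):
            perimeter_estimate(chain, (0.5, 0.8), "freeman")


def _stack(slices, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(np.stack(slices, axis=-1), spacing)


class TestSliceSelection:
    def test_sphere_selects_equator(self, sphere_volume):
        from headcirc.mask import extract_head_mask

        mask = extract_head_mask(sphere_volume)
        best = find_mhc_slice(mask)
        truth = sphere_volume.meta["manifest"]
        assert abs(best.slice_index - truth.equator_index) <= 1
        assert best.perimeter_mm[best.method] == pytest.approx(
            2 * math.pi * 80.0, rel=0.01
        )
        assert best.z_uncertainty_mm == pytest.approx(0.5)  # sz / 2

    def test_equal_areas_tie_breaks_to_lower_slice(self):
        disk = digitized_disk(10)
        empty = np.zeros_like(disk)
        mask = _stack([empty, disk, disk, empty])
        assert find_mhc_slice(mask).slice_index == 1

    def test_single_slice_mask(self):
        mask = _stack([digitized_disk(8)])
        assert find_mhc_slice(mask).slice_index == 0

    def test_empty_mask_rejected(self):
        mask = _stack([np.zeros((5, 5), bool)])
        with pytest.raises(ValueError, match="empty"):
            find_mhc_slice(mask)


class TestSliceProfile:
    def test_cylinder_slices_equal_area(self):
        disk = digitized_disk(30)
        mask = _stack([disk] * 6)
        profile = all_slice_profile(mask)
        areas = [s.area_mm2 for s in profile]
        assert np.ptp(areas) <= 0.005 * max(areas)

    def test_sphere_profile_is_unimodal(self, sphere_volume):
        from headcirc.mask import extract_head_mask

        mask = extract_head_mask(sphere_volume)
        areas = np.array([s.area_mm2 for s in all_slice_profile(mask)])
        peak = int(np.argmax(areas))
        assert np.all(np.diff(areas[: peak + 1]) >= 0)
        assert np.all(np.diff(areas[peak:]) <= 0)

    def test_profile_maximum_matches_mhc_slice(self, sphere_volume):
        from headcirc.mask import extract_head_mask

        mask = extract_head_mask(sphere_volume)
        profile = all_slice_profile(mask)
        best = find_mhc_slice(mask)
        assert max(s.area_mm2 for s in profile) == best.area_mm2

    def test_profile_csv_round_trip(self, tmp_path):
        import pandas as pd

        from headcirc.perimeter import profile_to_csv

        mask = _stack([digitized_disk(12)] * 3)
        profile = all_slice_profile(mask)
        f = tmp_path / "profile.csv"
        profile_to_csv(profile, f)
        df = pd.read_csv(f)
        assert list(df["slice_index"]) == [s.slice_index for s in profile]
        assert df["perimeter_mm"].tolist() == pytest.approx(
            [s.perimeter_mm[s.method] for s in profile]
        )
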