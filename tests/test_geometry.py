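import math

import numpy as np
import pytest
from scipy import ndimage

from minflat.geometry import (
    ShapeSpec,
    build_flattened,
    build_pill,
    match_stadium,
    stadium_polygon,
    stadium_volume,
)
from minflat.synthetic import make_outline, make_shape


def capsule_volume(length, radius):
    return math.pi * radius**2 * (length - 2 * radius) + 4 / 3 * math.pi * radius**3


def capsule_area(length, radius):
    return 2 * math.pi * radius * (length - 2 * radius) + 4 * math.pi * radius**2


class TestPill:
    def test_volume_and_area_match_closed_form(self):
        g = build_pill(4.0, 0.5, 0.05)
        assert g.total_volume == pytest.approx(capsule_volume(4.0, 0.5), rel=0.01)
        assert g.total_area == pytest.approx(capsule_area(4.0, 0.5), rel=0.01)

    def test_sphere_limiting_case(self):
        g = build_pill(1.0, 0.5, 0.05)
        assert g.total_volume == pytest.approx(4 / 3 * math.pi * 0.125, rel=0.01)
        assert g.total_area == pytest.approx(4 * math.pi * 0.25, rel=0.01)

    def test_volume_and_area_errors_shrink_with_dx(self):
        v_err, a_err = [], []
        for dx in (0.1, 0.05, 0.025):
            g = build_pill(4.0, 0.5, dx)
            v_err.append(abs(g.total_volume - capsule_volume(4.0, 0.5)))
            a_err.append(abs(g.total_area - capsule_area(4.0, 0.5)))
        assert v_err[0] > v_err[1] > v_err[2]
        assert a_err[0] > a_err[1] > a_err[2]

    def test_degenerate_dimensions_rejected(self):
        with pytest.raises(ValueError, match="length"):
            build_pill(0.8, 0.5, 0.05)

    def test_too_coarse_grid_rejected(self):
        with pytest.raises(ValueError, match="dx"):
            build_pill(4.0, 0.5, 0.3)

    def test_projection_symmetric_about_long_axis(self):
        g = build_pill(4.0, 0.5, 0.1)
        proj = g.volume.sum(axis=2)
        assert np.allclose(proj, proj[::-1, :])


class TestFlattened:
    def test_disc_rotation_symmetry(self):
        g = make_shape("disc", 0.1)
        quarter = np.rot90(g.mask, axes=(0, 1))
        assert g.mask.shape[0] == g.mask.shape[1]
        assert np.array_equal(g.mask, quarter)

    def test_disc_volume_matches_closed_form(self):
        # r-neighborhood of an eroded disc: Steiner formula
        g = make_shape("disc", 0.05)
        R, r = 1.5 - 0.2, 0.2
        v = 2 * r * math.pi * R**2 + math.pi * r**2 * (math.pi * R) + 4 / 3 * math.pi * r**3
        assert g.total_volume == pytest.approx(v, rel=0.01)

    def test_irregular_volume_matches_monte_carlo(self):
        """Voxel-summed volume agrees with Monte-Carlo integration of the
        same implicit shape function."""
        import shapely

        g = make_shape("shapeA", 0.1)
        outline = make_outline("shapeA")
        eroded = outline.buffer(-0.2)
        rng = np.random.default_rng(7)
        n = 400_000
        x0, y0, x1, y1 = outline.bounds
        pts = rng.uniform(
            [x0 - 0.25, y0 - 0.25, -0.2], [x1 + 0.25, y1 + 0.25, 0.2], (n, 3)
        )
        d2 = shapely.distance(shapely.points(pts[:, 0], pts[:, 1]), eroded)
        inside = np.hypot(d2, pts[:, 2]) < 0.2
        box = (x1 - x0 + 0.5) * (y1 - y0 + 0.5) * 0.4
        mc = inside.mean() * box
        mc_sd = box * math.sqrt(inside.mean() * (1 - inside.mean()) / n)
        assert abs(g.total_volume - mc) < max(0.01 * mc, 4 * mc_sd)

    def test_thickness_too_large_rejected(self):
        from shapely.geometry import Polygon

        thin = Polygon([(-0.1, -2), (0.1, -2), (0.1, 2), (-0.1, 2)])
        with pytest.raises(ValueError):
            build_flattened(thin, 0.4, 0.05)

    def test_thickness_is_0p4(self):
        g = make_shape("shapeA", 0.1)
        nz = g.mask.any(axis=(0, 1)).sum()
        assert nz * g.dx == pytest.approx(0.4, abs=g.dx)


class TestSymmetries:
    def test_stadium_has_three_mirror_planes(self):
        g = make_shape("stadiumA", 0.1)
        m = g.mask
        assert np.array_equal(m, m[::-1, :, :])
        assert np.array_equal(m, m[:, ::-1, :])
        assert np.array_equal(m, m[:, :, ::-1])

    @pytest.mark.parametrize("name", ["shapeA", "shapeB"])
    def test_irregular_has_exactly_one_in_plane_mirror(self, name):
        g = make_shape(name, 0.1)
        m = g.mask
        assert np.array_equal(m, m[::-1, :, :])       # across the long axis
        assert not np.array_equal(m, m[:, ::-1, :])   # but not end-to-end


class TestStadiumMatching:
    def test_matched_volume_and_aspect(self):
        ref = make_shape("shapeA", 0.1)
        spec = match_stadium(ref, 0.4)
        built = spec.build()
        assert built.total_volume == pytest.approx(ref.total_volume, rel=0.02)
        x0, y0, x1, y1 = spec.outline.bounds
        rx0, ry0, rx1, ry1 = ref.spec.outline.bounds
        assert (y1 - y0) / (x1 - x0) == pytest.approx(
            (ry1 - ry0) / (rx1 - rx0), rel=0.02
        )

    def test_root_find_agrees_with_brute_force_scan(self):
        ref = make_shape("shapeA", 0.1)
        spec = match_stadium(ref, 0.4)
        x0, y0, x1, y1 = spec.outline.bounds
        aspect = (y1 - y0) / (x1 - x0)
        widths = np.linspace(0.5, 6.0, 2000)
        vols = np.array([stadium_volume(aspect * w, w, 0.4) for w in widths])
        w_scan = widths[np.argmin(np.abs(vols - ref.total_volume))]
        assert (x1 - x0) == pytest.approx(w_scan, abs=widths[1] - widths[0])

    def test_aspect_one_degenerates_to_circle(self):
        poly = stadium_polygon(2.0, 2.0)
        x0, y0, x1, y1 = poly.bounds
        assert (x1 - x0) == pytest.approx(y1 - y0, rel=1e-6)
        # area of a circle of diameter 2
        assert poly.area == pytest.approx(math.pi, rel=1e-3)

    def test_infeasible_volume_rejected(self):
        ref = make_shape("shapeA", 0.1)
        with pytest.raises(ValueError):
            match_stadium(ref, 3.5)


class TestInvariants:
    @pytest.mark.parametrize("name", ["pill", "disc"])
    def test_single_connected_interior(self, name):
        g = make_shape(name, 0.1)
        _, n = ndimage.label(g.mask)
        assert n == 1

    def test_wall_distance_zero_at_membrane_rising_inward(self):
        g = build_pill(4.0, 0.5, 0.05)
        boundary = g.area > 0
        assert g.wall_distance[boundary].max() <= g.dx
        assert g.wall_distance[g.mask].max() > 5 * g.dx

    def test_membrane_voxels_touch_exterior(self):
        g = build_pill(4.0, 0.5, 0.1)
        exterior = ~g.mask
        touches = ndimage.binary_dilation(
            exterior, structure=ndimage.generate_binary_structure(3, 1)
        )
        assert np.all(touches[g.area > 0])

    def test_area_only_on_boundary_and_positive_volumes(self):
        g = make_shape("disc", 0.1)
        assert np.all(g.volume[g.mask] > 0)
        assert np.all(g.area[~g.mask] == 0)

    def test_shape_library_deterministic(self):
        a = make_shape("shapeA", 0.15)
        b = make_shape("shapeA", 0.15)
        assert np.array_equal(a.mask, b.mask)
        assert np.array_equal(a.volume, b.volume)
        assert np.array_equal(a.area, b.area)

    def test_hdf5_round_trip(self, tmp_path):
        from minflat.geometry import CellGeometry

        g = make_shape("disc", 0.1)
        g.save(tmp_path / "g.h5")
        g2 = CellGeometry.load(tmp_path / "g.h5")
        assert np.array_equal(g.mask, g2.mask)
        assert np.allclose(g.area, g2.area)
        assert g2.dx == g.dx


def test_shape_spec_validation():
    with pytest.raises(ValueError):
        ShapeSpec(kind="pill", dx=0.05, length=1.0, radius=0.6)
    with pytest.raises(ValueError):
        ShapeSpec(kind="banana", dx=0.05)
    with pytest.raises(ValueError):
        ShapeSpec(kind="pill", dx=-0.1, length=4.0, radius=0.5)
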