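"""Distance-map vertex, polar contour, eccentricity, protrusions and the
area/perimeter estimators, checked against analytic shapes."""

import numpy as np
import pytest
from scipy import ndimage

from cellactivity import morphology as mor
from cellactivity.phantoms import CellSpec, render_cell_mask
from cellactivity.tracking import LabelStack

PX_AREA = (640.0 / 1608.0) ** 2  # um^2 per pixel at the acquisition scale


class TestAreaPerimeter:
    def test_square_area_physical_units(self):
        mask = np.zeros((32, 32), bool)
        mask[10:20, 10:20] = True
        area, dA = mor.cell_area(mask, PX_AREA)
        assert area == pytest.approx(100 * PX_AREA)
        assert area == pytest.approx(15.84, abs=0.01)
        assert dA == 0.0

    def test_disk_area_analytic(self, disk_mask):
        area, _ = mor.cell_area(disk_mask, 1.0)
        assert area == pytest.approx(np.pi * 50 ** 2, rel=0.02)

    def test_constant_mask_zero_derivative(self, disk_mask):
        area, dA = mor.cell_area(disk_mask, 1.0, prev_area=np.pi * 2500,
                                 dt=0.0)
        assert dA == 0.0
        area2, dA2 = mor.cell_area(disk_mask, 1.0, prev_area=area, dt=1.0)
        assert dA2 == 0.0

    def test_disk_perimeter_crofton(self, disk_mask):
        perim, dP, shape = mor.cell_perimeter(disk_mask, 1.0)
        assert perim == pytest.approx(2 * np.pi * 50, rel=0.02)
        assert dP == 0.0

    def test_elongation_raises_shape_factor(self):
        line = np.zeros((8, 108), bool)
        line[3:4, 4:104] = True  # 1 x 100
        square = np.zeros((20, 20), bool)
        square[5:15, 5:15] = True  # 10 x 10, equal area
        _, _, s_line = mor.cell_perimeter(line, 1.0)
        _, _, s_square = mor.cell_perimeter(square, 1.0)
        assert s_line > s_square

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            mor.cell_area(np.zeros((8, 8), bool), 1.0)
        with pytest.raises(ValueError):
            mor.cell_perimeter(np.zeros((8, 8), bool), 1.0)


class TestDistanceMap:
    def test_disk_maximum_at_center(self, disk_mask):
        dm = mor.distance_map(disk_mask)
        assert dm.max_value == pytest.approx(50, abs=0.5)
        assert dm.max_position == (100, 100)

    def test_single_pixel(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        dm = mor.distance_map(mask)
        assert dm.max_value == 1.0

    def test_annulus_vertex_confined_to_mask(self):
        rr, cc = np.mgrid[0:128, 0:128]
        rho = np.hypot(rr - 64, cc - 64)
        ring = (rho >= 25) & (rho <= 40)
        dm = mor.distance_map(ring)
        assert ring[dm.max_position]  # on the mask...
        com = ndimage.center_of_mass(ring)
        assert not ring[int(round(com[0])), int(round(com[1]))]  # unlike CoM

    def test_zero_outside_mask(self, disk_mask):
        dm = mor.distance_map(disk_mask)
        assert (dm.grid[~disk_mask] == 0).all()


class TestRefineVertex:
    def test_disk_center_subpixel(self, disk_mask):
        v = mor.refine_vertex(mor.distance_map(disk_mask))
        assert np.hypot(v.refined[0] - 100, v.refined[1] - 100) < 0.5

    def test_ellipse_center(self, ellipse_mask):
        v = mor.refine_vertex(mor.distance_map(ellipse_mask))
        assert np.hypot(v.refined[0] - 100, v.refined[1] - 100) < 1.0

    def test_exact_gaussian_recovered_subpixel(self):
        rr, cc = np.mgrid[0:60, 0:60]
        surf = 10 * np.exp(-((rr - 20.3) ** 2 + (cc - 41.7) ** 2)
                           / (2 * 4.0 ** 2))
        pos = np.unravel_index(np.argmax(surf), surf.shape)
        dm = mor.DistanceMap(surf, (int(pos[0]), int(pos[1])),
                             float(surf[pos]))
        v = mor.refine_vertex(dm)
        assert np.hypot(v.refined[0] - 20.3, v.refined[1] - 41.7) < 0.1
        assert v.fit_sigma == pytest.approx(4.0, rel=0.05)

    def test_clipped_window_flagged(self):
        mask = np.zeros((20, 20), bool)
        mask[0:6, 0:6] = True
        v = mor.refine_vertex(mor.distance_map(mask))
        assert v.window_clipped


class TestPolarContour:
    def test_disk_constant_radius(self, disk_mask):
        v = mor.refine_vertex(mor.distance_map(disk_mask))
        pc = mor.polar_contour(disk_mask, v)
        assert np.all(np.abs(pc.distances - 50) <= 1.0)

    def test_ellipse_min_max_semi_axes(self, ellipse_mask):
        v = mor.refine_vertex(mor.distance_map(ellipse_mask))
        pc = mor.polar_contour(ellipse_mask, v)
        assert pc.distances.min() == pytest.approx(20, abs=1.0)
        assert pc.distances.max() == pytest.approx(40, abs=1.0)

    def test_vertex_outside_mask_errors(self, disk_mask):
        bad = mor.CellVertex((5, 5), (5.0, 5.0), 0.0, 1.0)
        with pytest.raises(ValueError):
            mor.polar_contour(disk_mask, bad)

    def test_contour_is_closed(self, disk_mask):
        v = mor.refine_vertex(mor.distance_map(disk_mask))
        pc = mor.polar_contour(disk_mask, v)
        gap = np.hypot(*(pc.points[0] - pc.points[-1]))
        assert gap < 2.0


class TestEccentricity:
    def test_disk_is_round(self, disk_mask):
        v = mor.refine_vertex(mor.distance_map(disk_mask))
        e = mor.eccentricity(mor.polar_contour(disk_mask, v))
        assert e.eps == pytest.approx(1.0, abs=0.1)
        assert np.hypot(*e.eps1) <= np.hypot(*e.eps2)

    def test_ellipse_matches_axis_ratio(self, ellipse_mask):
        v = mor.refine_vertex(mor.distance_map(ellipse_mask))
        e = mor.eccentricity(mor.polar_contour(ellipse_mask, v))
        assert e.eps == pytest.approx(0.5, rel=0.05)

    def test_protrusion_lowers_eccentricity(self, disk_mask, star_factory):
        v = mor.refine_vertex(mor.distance_map(disk_mask))
        e_disk = mor.eccentricity(mor.polar_contour(disk_mask, v))
        one_arm = render_cell_mask(
            CellSpec(body_radius=20, n_protrusions=1, protrusion_length=20),
            (100, 100), 0.0, (200, 200))
        v2 = mor.refine_vertex(mor.distance_map(one_arm))
        e_arm = mor.eccentricity(mor.polar_contour(one_arm, v2))
        assert e_arm.eps < e_disk.eps

    def test_monotone_under_elongation(self):
        prev = np.inf
        for ratio in (1.0, 0.8, 0.6, 0.4):
            mask = render_cell_mask(CellSpec(body_radius=40, axis_ratio=ratio),
                                    (100, 100), 0.0, (200, 200))
            v = mor.refine_vertex(mor.distance_map(mask))
            e = mor.eccentricity(mor.polar_contour(mask, v))
            assert e.eps <= prev + 0.02
            prev = e.eps

    def test_degenerate_contour_errors(self):
        pc = mor.PolarContour(np.zeros((4, 2)), np.zeros(4), np.ones(4),
                              (0.0, 0.0))
        with pytest.raises(ValueError):
            mor.eccentricity(pc)


class TestProtrusions:
    def test_bare_disk_zero(self, disk_mask):
        dm = mor.distance_map(disk_mask)
        v = mor.refine_vertex(dm)
        pc = mor.polar_contour(disk_mask, v)
        n, _ = mor.count_protrusions(pc, dm.max_value)
        assert n == 0

    @pytest.mark.parametrize("k", range(3, 9))
    def test_star_arm_count_exact(self, star_factory, k):
        mask = star_factory(k)
        dm = mor.distance_map(mask)
        pc = mor.polar_contour(mask, mor.refine_vertex(dm))
        n, tips = mor.count_protrusions(pc, dm.max_value)
        assert n == k
        tip_d = np.hypot(tips[:, 0] - 100, tips[:, 1] - 100)
        assert (tip_d > np.sqrt(2) * dm.max_value).all()

    def test_rotation_and_reflection_invariance(self, star_factory):
        mask = star_factory(5)
        counts = []
        for m in (mask, np.rot90(mask), np.fliplr(mask)):
            dm = mor.distance_map(m)
            pc = mor.polar_contour(m, mor.refine_vertex(dm))
            counts.append(mor.count_protrusions(pc, dm.max_value)[0])
        assert counts == [5, 5, 5]


class TestInvariances:
    @pytest.mark.parametrize("transform", [np.rot90, np.fliplr])
    def test_morphology_invariant_under_symmetry(self, star_factory,
                                                 transform):
        mask = star_factory(4)
        ref = mor.measure_cell(mask, 1.0)
        alt = mor.measure_cell(transform(mask).copy(), 1.0)
        assert alt.area == pytest.approx(ref.area, rel=0.01)
        assert alt.perimeter == pytest.approx(ref.perimeter, rel=0.05)
        assert alt.eccentricity == pytest.approx(ref.eccentricity, rel=0.05)
        assert alt.n_protrusions == ref.n_protrusions

    def test_vertex_more_stable_than_centroid(self):
        """Growing one protrusion barely moves the distance-map vertex
        while the weighted centroid drifts toward the new mass."""
        v_steps, com_steps = [], []
        prev_v = prev_com = None
        for length in (6, 12, 18, 24):
            mask = render_cell_mask(
                CellSpec(body_radius=20, n_protrusions=1,
                         protrusion_length=length),
                (100, 100), 0.0, (200, 200))
            v = mor.refine_vertex(mor.distance_map(mask)).refined
            com = ndimage.center_of_mass(mask)
            if prev_v is not None:
                v_steps.append(np.hypot(v[0] - prev_v[0], v[1] - prev_v[1]))
                com_steps.append(np.hypot(com[0] - prev_com[0],
                                          com[1] - prev_com[1]))
            prev_v, prev_com = v, com
        assert np.mean(v_steps) < np.mean(com_steps)


class TestMeasureFrame:
    def test_empty_frame_empty_list(self):
        stack = LabelStack(np.zeros((1, 32, 32), np.int32))
        assert mor.measure_frame(stack, 0, 1.0) == []

    def test_single_frame_no_derivatives(self, disk_mask):
        frames = np.where(disk_mask, 1, 0)[None].astype(np.int32)
        props = mor.measure_frame(LabelStack(frames), 0, 1.0)
        assert len(props) == 1
        assert props[0].dA_dt == 0.0 and props[0].dP_dt == 0.0

    def test_stack_table_has_derivatives(self, disk_mask):
        frames = np.repeat(np.where(disk_mask, 1, 0)[None], 3,
                           axis=0).astype(np.int32)
        df = mor.measure_stack(LabelStack(frames), 1.0)
        assert len(df) == 3
        assert df.loc[df["frame"] > 0, "dA_dt"].abs().max() == 0.0
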