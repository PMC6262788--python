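import numpy as np
import pytest

from foldshape import shape_metrics as sm
from foldshape.config import PipelineConfig
from foldshape.rasterize import boundary_pixels, supercover_line
from foldshape.types import CellMask2D

from oracles import brute_depth_chord, brute_width_perpendicular


def ellipse_mask(a_um, b_um, spacing, pad=3, angle_deg=0.0):
    """Rasterized ellipse with semi-axes a (x) and b (z), optionally rotated."""
    sx, sz = spacing
    nx = int(2 * a_um / sx) + 2 * pad + int(2 * b_um / sx)
    nz = int(2 * b_um / sz) + 2 * pad + int(2 * a_um / sz)
    zz, xx = np.mgrid[0:nz, 0:nx]
    cx, cz = (nx - 1) / 2, (nz - 1) / 2
    x = (xx - cx) * sx
    z = (zz - cz) * sz
    t = np.radians(angle_deg)
    xr = x * np.cos(t) + z * np.sin(t)
    zr = -x * np.sin(t) + z * np.cos(t)
    return CellMask2D((xr / a_um) ** 2 + (zr / b_um) ** 2 <= 1.0, spacing)


class TestSupercover:
    @pytest.mark.parametrize("seg", [(0, 0, 5, 3), (2, 7, 9, 1), (4, 4, 4, 9),
                                     (0, 0, 6, 6), (3, 1, 0, 8)])
    def test_endpoint_symmetry(self, seg):
        r0, c0, r1, c1 = seg
        fwd = set(supercover_line(r0, c0, r1, c1))
        rev = set(supercover_line(r1, c1, r0, c0))
        assert fwd == rev

    def test_contains_endpoints_and_bresenham(self):
        from skimage.draw import line
        rng = np.random.default_rng(3)
        for _ in range(50):
            r0, c0, r1, c1 = rng.integers(0, 20, 4)
            cells = set(supercover_line(r0, c0, r1, c1))
            assert (r0, c0) in cells and (r1, c1) in cells
            bres = set(zip(*line(r0, c0, r1, c1)))
            assert bres <= cells  # supercover is a superset

    def test_cells_form_connected_path(self):
        cells = supercover_line(0, 0, 7, 11)
        for a, b in zip(cells, cells[1:]):
            assert max(abs(a[0] - b[0]), abs(a[1] - b[1])) <= 1


class TestMaskArea:
    def test_pixel_count_times_spacing(self):
        mask = CellMask2D(np.ones((10, 10), bool), (0.5, 0.5))
        assert sm.mask_area(mask) == pytest.approx(25.0)

    def test_single_pixel(self):
        mask = CellMask2D(np.ones((1, 1), bool), (0.3, 0.6))
        assert sm.mask_area(mask) == pytest.approx(0.18)

    def test_ellipse_matches_pi_ab(self):
        mask = ellipse_mask(2.0, 5.0, (0.2, 0.2))
        assert sm.mask_area(mask) == pytest.approx(np.pi * 2 * 5, rel=0.05)


class TestDepthChord:
    def test_z_major_ellipse_depth_along_z(self):
        mask = ellipse_mask(2.0, 5.0, (0.2, 0.2))
        depth, angle = sm.max_depth_chord(mask)
        assert depth == pytest.approx(10.0, rel=0.05)
        assert angle <= 10.0

    def test_square_diagonal_at_inclusive_45(self):
        mask = CellMask2D(np.ones((12, 12), bool), (1.0, 1.0))
        depth, angle = sm.max_depth_chord(mask)
        assert angle == pytest.approx(45.0)
        assert depth == pytest.approx(12 * np.sqrt(2), abs=1.5)

    def test_one_pixel_wide_bar_full_length(self):
        mask = CellMask2D(np.ones((25, 1), bool), (1.0, 1.0))
        depth, angle = sm.max_depth_chord(mask)
        assert depth == pytest.approx(25.0)
        assert angle == 0.0

    def test_angle_bound_inclusive_never_exceeded(self, blob_masks):
        for mask in blob_masks:
            _, angle = sm.max_depth_chord(mask)
            assert angle <= 45.0 + 1e-9

    def test_rotation_covariance_of_bar(self):
        # a z-aligned bar rotated by θ ≤ 45° keeps its length, angle becomes θ
        n = 41
        for theta in (10.0, 25.0, 40.0):
            grid = np.zeros((n + 10, n + 10), bool)
            t = np.radians(theta)
            for k in range(n):
                r = int(round(5 + k * np.cos(t)))
                c = int(round(5 + k * np.sin(t)))
                grid[r, c - 1:c + 2] = True  # 3-px-wide rasterized bar
            mask = CellMask2D(grid, (1.0, 1.0))
            depth, angle = sm.max_depth_chord(mask)
            assert angle == pytest.approx(theta, abs=4.0)
            assert depth == pytest.approx(n, abs=3.0)


class TestWidthChord:
    def test_ellipse_width_perpendicular(self):
        mask = ellipse_mask(2.0, 5.0, (0.2, 0.2))
        depth, angle = sm.max_depth_chord(mask)
        width = sm.max_width_perpendicular(mask, angle)
        assert width == pytest.approx(4.0, rel=0.05)

    def test_circle_gives_isotropic_ratio(self):
        mask = ellipse_mask(4.0, 4.0, (0.2, 0.2))
        depth, angle = sm.max_depth_chord(mask)
        width = sm.max_width_perpendicular(mask, angle)
        assert depth == pytest.approx(8.0, rel=0.05)
        assert sm.xz_ratio(width, depth) == pytest.approx(1.0, abs=0.05)
        assert not sm.is_anisotropic(sm.xz_ratio(width, depth))

    def test_rotated_ellipse_matches_brute_force(self):
        mask = ellipse_mask(1.5, 3.0, (0.5, 0.5), angle_deg=30.0)
        depth, angle = sm.max_depth_chord(mask)
        width = sm.max_width_perpendicular(mask, angle)
        assert width == brute_width_perpendicular(mask.mask, mask.spacing,
                                                  angle)

    def test_x_axis_mode_ignores_depth_angle(self):
        mask = ellipse_mask(2.0, 5.0, (0.2, 0.2))
        w1 = sm.max_width_perpendicular(mask, 31.0, width_mode="x_axis")
        w2 = sm.max_width_perpendicular(mask, 0.0, width_mode="x_axis")
        assert w1 == w2


class TestChordOracles:
    """Implementation equals the exhaustive boundary-pair brute force."""

    def test_depth_equals_brute_force_on_random_blobs(self, blob_masks):
        for mask in blob_masks:
            got = sm.max_depth_chord(mask)
            expect = brute_depth_chord(mask.mask, mask.spacing)
            assert got == expect

    def test_width_equals_brute_force_on_random_blobs(self, blob_masks):
        for mask in blob_masks:
            _, angle = sm.max_depth_chord(mask)
            got = sm.max_width_perpendicular(mask, angle)
            expect = brute_width_perpendicular(mask.mask, mask.spacing, angle)
            assert got == expect

    def test_anisotropic_spacing_angles_physical(self):
        # a bar along z at (sx, sz) = (0.2, 0.5): 45° bound applies in μm
        grid = np.zeros((20, 20), bool)
        for k in range(15):
            grid[k, k] = True  # pixel-diagonal, but physically z-dominated
        grid[0, 1] = grid[1, 0] = True
        mask = CellMask2D(grid, (0.2, 0.5))
        got = sm.max_depth_chord(mask)
        expect = brute_depth_chord(grid, (0.2, 0.5))
        assert got == expect
        assert got[1] == pytest.approx(np.degrees(np.arctan2(0.2, 0.5)),
                                       abs=5)


class TestXZRatio:
    def test_examples(self):
        assert sm.xz_ratio(4.0, 10.0) == pytest.approx(0.4)
        assert sm.is_anisotropic(0.4)
        assert sm.xz_ratio(7.0, 7.0) == pytest.approx(1.0)
        assert not sm.is_anisotropic(1.0)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            sm.xz_ratio(10.0, 0.0)


class TestMeasureCellShape:
    def test_basal_ratio_recovered(self, small_epithelium):
        _, stack, labels, truth = small_epithelium
        row = truth["cells"].iloc[0]
        rec = sm.measure_cell_shape(stack, labels, int(row["cell_id"]),
                                    "basal")
        assert rec.xz_ratio == pytest.approx(row["basal_ratio"], abs=0.05)
        assert rec.anisotropic

    def test_isotropic_cell_ratio_one(self):
        from foldshape.synthetic_data import (EpitheliumParams,
                                              generate_epithelium_stack)
        p = EpitheliumParams(n_cells_per_side=0, apical_xz_ratio=1.0,
                             basal_xz_ratio=1.0, fold_angle=180.0, seed=1)
        stack, labels, _ = generate_epithelium_stack(p)
        for surface in ("apical", "basal"):
            rec = sm.measure_cell_shape(stack, labels, 1, surface)
            assert rec.xz_ratio == pytest.approx(1.0, abs=0.05)

    def test_missing_cell_at_slice_names_stage(self):
        import numpy as np
        from foldshape.types import CellLabelVolume, ImageStack3D
        lab = np.zeros((30, 60, 40), dtype=np.int32)
        lab[5:25, 10:50, 15:25] = 2
        lab[5:25, 40:48, 15:25] = 0   # interior gap covering the basal sixth
        vol = CellLabelVolume(lab, (0.5, 0.5, 0.5))
        stack = ImageStack3D(np.zeros_like(lab, dtype=float), vol.spacing)
        with pytest.raises(ValueError, match="extract_xz_slice"):
            sm.measure_cell_shape(stack, vol, 2, "basal")


class TestMhbAngle:
    def test_perpendicular_rays(self):
        s = np.arange(1, 11, dtype=float)
        left = np.stack([-s[::-1] / np.sqrt(2), s[::-1] / np.sqrt(2)], axis=1)
        right = np.stack([s / np.sqrt(2), s / np.sqrt(2)], axis=1)
        pts = np.concatenate([left, [[0.0, 0.0]], right])
        res = sm.measure_mhb_angle(pts, vertex_index=10)
        assert res.angle_deg == pytest.approx(90.0, abs=1e-6)

    def test_collinear_points_give_180(self):
        xs = np.linspace(-10, 10, 21)
        pts = np.stack([xs, np.zeros_like(xs)], axis=1)
        res = sm.measure_mhb_angle(pts, vertex_index=10)
        assert res.angle_deg == pytest.approx(180.0)

    def test_generated_fold_angle_recovered(self):
        from foldshape.synthetic_data import (EpitheliumParams,
                                              generate_epithelium_stack)
        p = EpitheliumParams(n_cells_per_side=1, fold_angle=120.0, seed=2)
        _, _, truth = generate_epithelium_stack(p)
        surf = truth["basal_surface"]
        res = sm.measure_mhb_angle(surf[["x_um", "y_um"]].to_numpy(),
                                   surf.attrs["vertex_index"])
        assert res.angle_deg == pytest.approx(120.0, abs=5.0)

    def test_insufficient_points_rejected(self):
        pts = np.array([[-1.0, 1.0], [0.0, 0.0], [1.0, 1.0], [2.0, 2.0],
                        [3.0, 3.0]])
        with pytest.raises(ValueError, match="left"):
            sm.measure_mhb_angle(pts, vertex_index=1)
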