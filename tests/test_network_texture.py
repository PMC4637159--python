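"""Texture placement, the extended texture function F, and shell projection."""

import numpy as np
import pandas as pd
import pytest
from PIL import Image
from scipy import ndimage

from purkinje3d.chart import from_curvilinear, to_curvilinear_grid
from purkinje3d.network_texture import (
    NetworkImage,
    PlacementRect,
    _cylinder_to_pixels,
    evaluate_F,
    pixel_to_cylinder,
    project_network,
    read_network,
)


class TestReadNetwork:
    def _write(self, tmp_path, mask, rows):
        img = (mask.T[::-1, :] * 255).astype(np.uint8)
        Image.fromarray(img, mode="L").save(tmp_path / "net.png")
        pd.DataFrame(rows).to_csv(tmp_path / "sites.csv", index=False)
        return tmp_path / "net.png", tmp_path / "sites.csv"

    @pytest.mark.parametrize("n_sites", [130, 100])
    def test_site_counts_of_digitized_branches(self, tmp_path, n_sites):
        # synthetic stand-ins sized like the left (130) and right (100)
        # ventricular branch digitizations
        rng = np.random.default_rng(n_sites)
        mask = np.zeros((200, 150), bool)
        mask[10:190, 75] = True
        u1 = rng.integers(10, 190, n_sites)
        rows = [
            {"site_id": i, "u1": int(u), "u2": 75, "kind": "coupling"}
            for i, u in enumerate(u1)
        ]
        png, csv = self._write(tmp_path, mask, rows)
        net = read_network(png, csv)
        assert net.n_sites == n_sites

    def test_empty_image_with_no_sites_is_valid(self, tmp_path):
        png, csv = self._write(
            tmp_path, np.zeros((10, 10), bool),
            [{"site_id": 0, "u1": 1, "u2": 1, "kind": "bundle_branch"}],
        )
        net = read_network(png, csv)
        assert net.n_sites == 0 and not net.mask.any()
        assert net.bundle_branch is not None

    def test_site_outside_raster_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            NetworkImage(mask=np.ones((4, 4), bool), sites=[[10.0, 1.0]])

    def test_orientation_lower_left_origin(self, tmp_path):
        # a single lit pixel at (u1=2, u2=0) sits in the bottom raster row
        mask = np.zeros((5, 4), bool)
        mask[2, 0] = True
        png, csv = self._write(tmp_path, mask, [{"site_id": 0, "u1": 2, "u2": 0}])
        net = read_network(png, csv)
        assert net.mask[2, 0] and net.mask.sum() == 1


class TestPixelToCylinder:
    rect = PlacementRect(a=1.0, b=3.0, c=-0.5, d=0.5)

    def test_corners(self):
        assert pixel_to_cylinder(self.rect, 10, 20, (0, 0)) == (1.0, -0.5)
        assert pixel_to_cylinder(self.rect, 10, 20, (10, 20)) == (3.0, 0.5)

    def test_midpoint_linearity(self):
        s, z = pixel_to_cylinder(self.rect, 10, 20, (5, 10))
        assert (s, z) == (2.0, 0.0)

    def test_wrap_modulo_L(self):
        s, _ = pixel_to_cylinder(self.rect, 10, 20, (10, 0), wrap_length=2.5)
        assert s == pytest.approx(0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            pixel_to_cylinder(self.rect, 10, 20, (11, 0))

    def test_aspect_preservation_check(self):
        rect = PlacementRect(a=0, b=2, c=0, d=1, preserve_aspect=True)
        rect.check_aspect(100, 50)  # 2/1 == 100/50, fine
        with pytest.raises(ValueError, match="aspect"):
            rect.check_aspect(100, 80)


class TestEvaluateF:
    def test_outside_rect_is_zero(self, circle_chart):
        net = NetworkImage(mask=np.ones((8, 8), bool), sites=np.zeros((0, 2)))
        rect = PlacementRect(a=0.0, b=1.0, c=0.0, d=1.0)
        assert evaluate_F(circle_chart, rect, net, [1.2, 0.0, 5.0]) == 0

    def test_constant_along_trajectories(self, circle_chart, circle_curve):
        # same (s, z) at two different t values gives the same value
        rng = np.random.default_rng(2)
        net = NetworkImage(mask=rng.random((32, 32)) > 0.5, sites=np.zeros((0, 2)))
        rect = PlacementRect(a=0.0, b=circle_curve.L, c=0.0, d=1.0)
        for s in rng.uniform(0, circle_curve.L, 20):
            z = rng.uniform(0.05, 0.95)
            p1 = from_curvilinear(circle_chart, s, -0.25)
            p2 = from_curvilinear(circle_chart, s, 0.55)
            v1 = evaluate_F(circle_chart, rect, net, [p1[0], p1[1], z])
            v2 = evaluate_F(circle_chart, rect, net, [p2[0], p2[1], z])
            assert v1 == v2

    def test_cylinder_surface_matches_analytic_wrap(self, cylinder_mapped):
        # analytic oracle on the exact cylinder: s = R * theta directly
        mg = cylinder_mapped
        phase, chart, rect, net = mg.phase, mg.chart, mg.rect, mg.network
        sp = phase.spacing
        idx = mg.shell.indices()
        rng = np.random.default_rng(4)
        pick = rng.choice(len(idx), 1000, replace=False)
        c = (np.array(phase.shape[:2]) - 1) / 2 * sp
        agree = total = 0
        for i, j, k in idx[pick]:
            p = np.array([i * sp, j * sp, k * sp])
            theta = np.mod(np.arctan2(p[1] - c[1], p[0] - c[0]), 2 * np.pi)
            s_analytic = theta / (2 * np.pi) * chart.wrap_length
            u1, u2 = _cylinder_to_pixels(
                chart, rect, net, np.array([s_analytic]), np.array([p[2]])
            )
            if not (np.isfinite(u1[0]) and np.isfinite(u2[0])):
                continue
            pi = min(int(u1[0]), net.W - 1)
            pj = min(int(u2[0]), net.H - 1)
            # raster-edge pixels may legitimately differ: only compare where
            # the texture is locally uniform around the analytic pixel
            patch = net.mask[
                max(0, pi - 1): pi + 2, max(0, pj - 1): pj + 2
            ]
            if patch.any() != patch.all():
                continue
            total += 1
            agree += evaluate_F(chart, rect, net, p) == bool(net.mask[pi, pj])
        assert total > 500
        assert agree / total >= 0.99


class TestProjection:
    def test_empty_texture_empty_projection(self, cylinder_mapped):
        mg = cylinder_mapped
        empty = NetworkImage(mask=np.zeros((16, 16), bool), sites=np.zeros((0, 2)))
        proj = project_network(mg.chart, mg.rect, empty, mg.shell, mg.phase)
        assert proj.voxels.count == 0
        assert len(proj.site_voxels) == 0 and len(proj.unmapped_sites) == 0

    def test_vertical_fiber_lands_at_one_angle(self, cylinder_mapped):
        mg = cylinder_mapped
        mask = np.zeros((96, 96), bool)
        mask[30, :] = True
        net = NetworkImage(mask=mask, sites=np.array([[30.5, 1.0]]))
        proj = project_network(mg.chart, mg.rect, net, mg.shell, mg.phase)
        idx = proj.voxels.indices()
        sp = mg.phase.spacing
        c = (np.array(mg.phase.shape[:2]) - 1) / 2 * sp
        theta = np.arctan2(idx[:, 1] * sp - c[1], idx[:, 0] * sp - c[0])
        spread = np.ptp(np.unwrap(np.sort(theta)))
        assert spread < np.deg2rad(8)  # within about one voxel of arc
        zlo = mg.rect.c / sp
        zhi = mg.rect.d / sp
        assert idx[:, 2].min() <= zlo + 1 and idx[:, 2].max() >= zhi - 1

    def test_site_count_conservation(self, cylinder_mapped, ellipsoid_mapped):
        for mg in (cylinder_mapped, ellipsoid_mapped):
            proj = mg.projected
            assert len(proj.site_voxels) + len(proj.unmapped_sites) == mg.network.n_sites

    def test_network_voxels_inside_shell(self, cylinder_mapped, ellipsoid_mapped):
        for mg in (cylinder_mapped, ellipsoid_mapped):
            assert np.all(mg.shell.flags[mg.projected.voxels.flags])

    def test_site_voxels_are_network_voxels(self, cylinder_mapped):
        proj = cylinder_mapped.projected
        for vox in proj.site_voxels.values():
            assert proj.voxels.flags[vox]

    def test_projected_network_is_face_connected(self, cylinder_mapped):
        labels, n = ndimage.label(
            cylinder_mapped.projected.voxels.flags,
            ndimage.generate_binary_structure(3, 1),
        )
        assert n == 1

    def test_coverage_monotone_in_rect(self, cylinder_mapped):
        # enlarging the placement rectangle never loses projected voxels
        mg = cylinder_mapped
        r0 = mg.rect
        small = PlacementRect(r0.a, r0.b, r0.c + 0.1, r0.d - 0.1)
        p_small = project_network(mg.chart, small, mg.network, mg.shell, mg.phase)
        p_big = mg.projected
        assert p_big.voxels.count >= p_small.voxels.count


class TestRoundTrip:
    def test_pixel_voxel_pixel_recovery(self, cylinder_mapped):
        # exact-cylinder round trip: >= 99% of fiber pixels within 1.5 px
        from purkinje3d.network_texture import map_pixels_to_voxels

        mg = cylinder_mapped
        sp = mg.phase.spacing
        fiber = np.argwhere(mg.network.mask).astype(float) + 0.5
        voxs = map_pixels_to_voxels(
            mg.chart, mg.rect, mg.network, mg.shell, mg.phase, fiber
        )
        errs = []
        for px, vox in zip(fiber, voxs):
            if vox is None:
                errs.append(np.inf)
                continue
            p = np.array([[vox[0] * sp, vox[1] * sp]])
            s, _ = to_curvilinear_grid(mg.chart, p)
            u1, u2 = _cylinder_to_pixels(
                mg.chart, mg.rect, mg.network, s, np.array([vox[2] * sp])
            )
            err = np.hypot(u1[0] - px[0], u2[0] - px[1])
            errs.append(err if np.isfinite(err) else np.inf)
        errs = np.asarray(errs)
        assert np.mean(errs <= 1.5) >= 0.99
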