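"""Localization, depth calibration/inversion, registration, scene assembly
and the volume-rendering reductions."""

import numpy as np
import pytest

from translume import reconstruct3d as r3d
from translume.errors import ConfigurationError, DegenerateGeometryError, DomainError
from translume.spectral import FeatureMap


def fmap(values):
    v = np.asarray(values, float)
    return FeatureMap(
        v, 2.0 * np.arange(v.shape[0]), 2.0 * np.arange(v.shape[1]), "DI"
    )


class TestLocalizeProbe:
    def test_single_hot_pixel(self):
        v = np.zeros((9, 9))
        v[3, 5] = 100.0
        ests = r3d.localize_probe(fmap(v))
        assert len(ests) == 1
        assert ests[0].xy_mm == (6.0, 10.0)

    def test_symmetric_blob_centroid_at_center(self):
        x = np.arange(11)
        u, w = np.meshgrid(x, x, indexing="ij")
        v = np.exp(-((u - 5.0) ** 2 + (w - 5.0) ** 2) / 4.0)
        ests = r3d.localize_probe(fmap(v), detection_threshold=0.1)
        assert len(ests) == 1
        assert ests[0].xy_mm[0] == pytest.approx(10.0, abs=1e-9)
        assert ests[0].xy_mm[1] == pytest.approx(10.0, abs=1e-9)

    def test_nothing_above_threshold_gives_empty_list(self):
        assert r3d.localize_probe(fmap(np.ones((4, 4))), detection_threshold=10.0) == []

    def test_two_separated_blobs_found_with_threshold_frac(self):
        v = np.zeros((12, 6))
        v[2, 2] = v[9, 3] = 50.0
        ests = r3d.localize_probe(fmap(v), threshold_frac=0.5)
        assert len(ests) == 2

    def test_merge_duplicates_across_maps(self):
        v = np.zeros((8, 8))
        v[4, 4] = 10.0
        a = r3d.localize_probe(fmap(v))
        v2 = np.zeros((8, 8))
        v2[4, 5] = 30.0
        b = r3d.localize_probe(fmap(v2))
        merged = r3d.merge_probe_estimates(a + b, merge_radius_mm=4.0)
        assert len(merged) == 1
        assert merged[0].peak_value == 30.0  # brightest kept


class TestDepthCalibration:
    def test_linear_samples_full_validity_exact(self):
        d = np.array([2.0, 10.0, 20.0, 30.0, 40.0])
        cal = r3d.build_depth_calibration(d, 0.5 * d)
        assert cal.validity == (2.0, 40.0)
        assert not cal.saturated
        assert cal.feature_at(24.0) == pytest.approx(12.0)

    def test_plateau_is_trimmed_from_validity(self):
        d = np.array([2.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0])
        f = np.array([1.0, 5.0, 10.0, 15.0, 20.0, 20.05, 20.08])
        with np.errstate(all="ignore"):
            cal = r3d.build_depth_calibration(d, f, slope_floor=0.05)
        assert cal.validity[1] == 40.0
        assert cal.saturated

    def test_two_samples_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            r3d.build_depth_calibration([2.0, 5.0], [1.0, 2.0])

    def test_decreasing_feature_supported(self):
        d = np.array([5.0, 10.0, 20.0, 30.0])
        f = np.array([100.0, 80.0, 40.0, 10.0])
        cal = r3d.build_depth_calibration(d, f)
        assert not cal.increasing
        est = r3d.invert_depth(60.0, cal)
        assert 10.0 < est.depth_mm < 20.0


class TestInvertDepth:
    def _cal(self):
        d = np.array([2.0, 5.0, 10.0, 20.0, 30.0, 40.0])
        return r3d.build_depth_calibration(d, 0.5 * d)

    def test_knot_values_invert_exactly(self):
        cal = self._cal()
        for d in cal.knot_depth_mm:
            est = r3d.invert_depth(cal.feature_at(d), cal)
            assert est.depth_mm == pytest.approx(d, abs=1e-12)
            assert not est.extrapolated

    def test_linear_closed_form(self):
        est = r3d.invert_depth(10.0, self._cal())
        assert est.depth_mm == pytest.approx(20.0)

    def test_out_of_range_clamps_and_flags(self):
        est = r3d.invert_depth(0.1, self._cal())
        assert est.extrapolated
        assert est.depth_mm == pytest.approx(2.0)

    def test_saturation_region_is_unreliable(self):
        d = np.array([2.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0])
        f = np.array([1.0, 5.0, 10.0, 15.0, 20.0, 20.05, 20.08])
        with np.errstate(all="ignore"):
            cal = r3d.build_depth_calibration(d, f, slope_floor=0.05)
        est = r3d.invert_depth(20.06, cal)
        assert not est.reliable
        assert est.depth_mm is None

    def test_uncertainty_maps_feature_noise_through_slope(self):
        est = r3d.invert_depth(10.0, self._cal(), feature_noise_sd=0.5)
        assert est.uncertainty_mm == pytest.approx(1.0)  # slope 0.5 mm/mm


class TestRegisterFiducials:
    MARKERS = np.array(
        [[0.0, 0.0, 0.0], [10.0, 0.0, 1.0], [0.0, 8.0, 2.0], [6.0, 7.0, 9.0]]
    )

    def test_identity(self):
        tr = r3d.register_fiducials(self.MARKERS, self.MARKERS)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(tr.translation, 0.0, atol=1e-12)
        assert tr.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_recovered_exactly(self):
        tr = r3d.register_fiducials(self.MARKERS, self.MARKERS + [1.0, 2.0, 3.0])
        assert np.allclose(tr.translation, [1.0, 2.0, 3.0], atol=1e-12)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-12)

    def test_rotation_with_noise_recovered(self):
        rng = np.random.default_rng(42)
        theta = np.deg2rad(30.0)
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        target = self.MARKERS @ rot.T + rng.normal(0, 0.1, self.MARKERS.shape)
        tr = r3d.register_fiducials(self.MARKERS, target)
        angle = np.rad2deg(np.arccos(np.clip((np.trace(tr.rotation) - 1) / 2, -1, 1)))
        assert angle == pytest.approx(30.0, abs=1.0)
        assert tr.rmsd < 0.2

    def test_no_reflection_allowed(self):
        mirrored = self.MARKERS * [1.0, 1.0, -1.0]
        tr = r3d.register_fiducials(self.MARKERS, mirrored)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0)

    def test_collinear_markers_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            r3d.register_fiducials(line, line)

    def test_transform_is_an_isometry(self, rng):
        src = rng.uniform(-10, 10, (6, 3))
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), 0.0, np.sin(theta)],
                [0.0, 1.0, 0.0],
                [-np.sin(theta), 0.0, np.cos(theta)],
            ]
        )
        tr = r3d.register_fiducials(src, src @ rot.T + [3.0, -1.0, 2.0])
        pts = rng.uniform(-5, 5, (10, 3))
        moved = tr.apply(pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d1 = np.linalg.norm(moved[:, None] - moved[None], axis=-1)
        assert np.allclose(d1, d0, rtol=1e-10, atol=1e-10)


class TestReconstructScene:
    def _flat_surface(self, z=10.0):
        g = np.arange(0.0, 21.0, 1.0)
        gx, gy = np.meshgrid(g, g, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)])
        return r3d.SurfacePointCloud(pts)

    def _probe(self, x, y, depth):
        return r3d.ProbeEstimate(
            (x, y), (x, x, y, y), 1.0, 1.0, ("DI",), depth_mm=depth
        )

    def test_flat_surface_depth_subtraction(self):
        scene = r3d.reconstruct_scene(self._flat_surface(10.0), [self._probe(5, 5, 4)])
        assert scene.probe_table.loc[0, "z_mm"] == pytest.approx(6.0)

    def test_hemisphere_surface_analytic_height(self):
        radius = 15.0
        g = np.arange(-15.0, 15.5, 0.5)
        gx, gy = np.meshgrid(g, g, indexing="ij")
        gz = np.sqrt(np.clip(radius**2 - gx**2 - gy**2, 0.0, None))
        cloud = r3d.SurfacePointCloud(
            np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        )
        scene = r3d.reconstruct_scene(cloud, [self._probe(3.0, 4.0, 5.0)])
        z_expected = np.sqrt(radius**2 - 9.0 - 16.0) - 5.0
        assert scene.probe_table.loc[0, "z_mm"] == pytest.approx(z_expected, abs=0.1)

    def test_empty_probe_list_gives_surface_only(self):
        scene = r3d.reconstruct_scene(self._flat_surface(), [])
        assert len(scene.probe_table) == 0

    def test_outside_footprint_flagged(self):
        scene = r3d.reconstruct_scene(self._flat_surface(), [self._probe(50, 50, 2)])
        assert "outside_footprint" in scene.probe_table.loc[0, "flags"]


class TestProjections:
    def test_ones_cube_z_projection(self):
        assert np.array_equal(
            r3d.project_cube(np.ones((2, 3, 4)), "z"), np.full((2, 3), 4.0)
        )

    def test_mip_finds_single_max_voxel(self):
        cube = np.zeros((3, 3, 5))
        cube[1, 2, 3] = 9.0
        img = r3d.mip(cube, "z")
        assert img[1, 2] == 9.0
        assert img.sum() == 9.0

    def test_matches_loop_oracle_and_conserves_totals(self, rng):
        cube = rng.uniform(0, 1, (3, 4, 5))
        for axis, ax in (("x", 0), ("y", 1), ("z", 2)):
            proj = r3d.project_cube(cube, axis)
            oracle = np.zeros(tuple(s for i, s in enumerate(cube.shape) if i != ax))
            for idx in np.ndindex(cube.shape):
                out_idx = tuple(v for i, v in enumerate(idx) if i != ax)
                oracle[out_idx] += cube[idx]
            assert np.allclose(proj, oracle)
            assert proj.sum() == pytest.approx(cube.sum(), rel=1e-12)

    def test_bad_axis_is_domain_error(self):
        with pytest.raises(DomainError):
            r3d.project_cube(np.ones((2, 2, 2)), "w")

    def test_opacity_mask_default_threshold(self):
        cube = np.array([[[0.2, 0.5, 1.0]]])
        assert r3d.opacity_mask(cube).tolist() == [[[False, True, True]]]


class TestPointCloudIO:
    def test_ply_roundtrip_with_fiducials(self, tmp_path, rng):
        cloud = r3d.SurfacePointCloud(
            rng.uniform(0, 10, (20, 3)),
            fiducials={"F1": np.array([1.0, 2.0, 3.0]), "F2": np.array([4.0, 5.0, 6.0])},
        )
        path = tmp_path / "cloud.ply"
        r3d.write_point_cloud(path, cloud)
        back = r3d.read_point_cloud(path)
        assert np.allclose(back.points, cloud.points, atol=1e-4)
        assert set(back.fiducials) == {"F1", "F2"}
        assert np.allclose(back.fiducials["F1"], [1.0, 2.0, 3.0])
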