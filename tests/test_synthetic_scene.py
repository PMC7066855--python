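import numpy as np
import pytest
from scipy import ndimage, stats

from spheroplane import (
    ImagingConfig,
    SceneConfig,
    generate_block_scene,
    generate_plate_series,
    render_stack,
)
from spheroplane.synthetic_scene import scene_centroids_from_csv, scene_to_csv


def full_grid_config(**overrides) -> SceneConfig:
    defaults = dict(plane_p0=500.0, rng_seed=7)
    defaults.update(overrides)
    return SceneConfig(**defaults)


class TestSceneConfig:
    def test_pitch_must_exceed_diameter(self):
        with pytest.raises(ValueError, match="pitch"):
            SceneConfig(pitch=400.0, mean_diameter=500.0)

    def test_capture_prob_range(self):
        with pytest.raises(ValueError, match="capture_prob"):
            SceneConfig(capture_prob=1.2)

    def test_capture_matrix_shape(self):
        with pytest.raises(ValueError, match="capture_prob matrix"):
            SceneConfig(capture_prob=np.ones((4, 4))).capture_matrix()

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(z_noise_sd=-1.0)


class TestGenerateBlockScene:
    def test_noiseless_planar_full_capture(self):
        scene = generate_block_scene(full_grid_config(capture_prob=1.0))
        assert scene.n_spheroids == 96
        assert scene.captured.all()
        assert all(s.centroid[2] == 500.0 for s in scene.spheroids)

    def test_empty_scene(self):
        scene = generate_block_scene(full_grid_config(capture_prob=0.0))
        assert scene.n_spheroids == 0
        assert not scene.captured.any()

    def test_capture_fraction_binomial(self):
        # 6 scenes x 96 wells = 576 Bernoulli(0.8) trials; [0.70, 0.90]
        # covers far beyond the exact binomial 99.9% interval
        lo = stats.binom.ppf(0.0005, 576, 0.8) / 576
        hi = stats.binom.ppf(0.9995, 576, 0.8) / 576
        assert 0.70 < lo and hi < 0.90
        captured = sum(
            generate_block_scene(full_grid_config(capture_prob=0.8, rng_seed=s)).n_spheroids
            for s in range(6)
        )
        assert 0.70 <= captured / 576 <= 0.90

    def test_centroids_exactly_on_plane(self):
        cfg = full_grid_config(plane_p0=812.76, plane_px=-0.006266, plane_py=-0.01693)
        scene = generate_block_scene(cfg)
        for s in scene.spheroids:
            x, y, z = s.centroid
            assert z == pytest.approx(812.76 - 0.006266 * x - 0.01693 * y, abs=1e-9)

    def test_parabolic_bowing_forms_depression(self):
        cfg = full_grid_config(bowl_coeff=1e-6, plane_p0=900.0)
        scene = generate_block_scene(cfg)
        zs = {s.well_id: s.centroid[2] for s in scene.spheroids}
        # row A across columns: minimum near the grid midline in x
        row_a = [zs[f"A{c}"] for c in range(1, 13)]
        assert min(row_a) < row_a[0] and min(row_a) < row_a[-1]
        assert np.argmin(row_a) in (5, 6)

    def test_z_noise_changes_z_only(self):
        cfg = full_grid_config(z_noise_sd=50.0, rng_seed=3)
        scene = generate_block_scene(cfg)
        base = generate_block_scene(full_grid_config(rng_seed=3))
        for a, b in zip(scene.spheroids, base.spheroids):
            assert a.centroid[:2] == b.centroid[:2]
            assert a.centroid[2] != b.centroid[2]

    def test_determinism_same_seed(self):
        a = generate_block_scene(full_grid_config(capture_prob=0.8, z_noise_sd=20.0))
        b = generate_block_scene(full_grid_config(capture_prob=0.8, z_noise_sd=20.0))
        np.testing.assert_array_equal(a.captured, b.captured)
        np.testing.assert_array_equal(a.centroids(), b.centroids())

    def test_different_seeds_differ(self):
        a = generate_block_scene(full_grid_config(capture_prob=0.8, rng_seed=1))
        b = generate_block_scene(full_grid_config(capture_prob=0.8, rng_seed=2))
        assert not np.array_equal(a.captured, b.captured)

    def test_per_well_substreams_stable_under_capture_pattern(self):
        # masking some wells must not shift the draws of the remaining wells
        p = np.ones((8, 12))
        p[0, :] = 0.0
        masked = generate_block_scene(full_grid_config(capture_prob=p, z_noise_sd=30.0))
        full = generate_block_scene(full_grid_config(capture_prob=1.0, z_noise_sd=30.0))
        full_by_well = {s.well_id: s for s in full.spheroids}
        for s in masked.spheroids:
            assert s.centroid == full_by_well[s.well_id].centroid

    def test_protrusion_rejected(self):
        cfg = full_grid_config(plane_p0=100.0)  # 250 μm radius around z=100
        with pytest.raises(ValueError, match="protrude"):
            generate_block_scene(cfg, field_z=1000.0)

    def test_scene_csv_round_trip(self, tmp_path):
        scene = generate_block_scene(full_grid_config(capture_prob=0.8))
        scene_to_csv(scene, tmp_path / "scene.csv")
        df = scene_centroids_from_csv(tmp_path / "scene.csv")
        assert len(df) == scene.n_spheroids
        np.testing.assert_allclose(
            df[["cx_um", "cy_um", "cz_um"]].to_numpy(), scene.centroids()
        )


def single_sphere_setup(radius=150.0, voxel_xy=10.0, dz=30.0, **imaging_kw):
    cfg = SceneConfig(
        grid_rows=1, grid_cols=1, pitch=radius * 4, mean_diameter=radius * 2,
        plane_p0=400.0, grid_origin_x=400.0, grid_origin_y=400.0, rng_seed=0,
    )
    imaging = ImagingConfig(
        voxel_xy=voxel_xy, section_thickness=dz,
        field_x=800.0, field_y=800.0, field_z=800.0, **imaging_kw,
    )
    return generate_block_scene(cfg), imaging


class TestRenderStack:
    def test_single_sphere_one_component(self):
        scene, imaging = single_sphere_setup()
        stack = render_stack(scene, imaging)
        fg = stack.voxels > imaging.foreground_intensity / 2
        _, n = ndimage.label(fg, structure=ndimage.generate_binary_structure(3, 3))
        assert n == 1

    def test_empty_scene_all_zero(self):
        cfg = SceneConfig(capture_prob=0.0, plane_p0=500.0)
        scene = generate_block_scene(cfg)
        stack = render_stack(scene, ImagingConfig(voxel_xy=100.0))
        assert not stack.voxels.any()

    def test_attenuation_dims_deep_sections(self):
        scene, imaging = single_sphere_setup(attenuation_length=200.0)
        stack = render_stack(scene, imaging)
        occupied = np.where(stack.voxels.any(axis=(1, 2)))[0]
        deepest, shallowest = occupied[0], occupied[-1]  # low z = far from objective

        def mean_fg(k):
            sl = stack.voxels[k]
            return sl[sl > 0].mean()

        assert mean_fg(deepest) < mean_fg(shallowest)

    def test_no_attenuation_uniform_intensity(self):
        scene, imaging = single_sphere_setup()
        stack = render_stack(scene, imaging)
        fg = stack.voxels[stack.voxels > 0]
        assert np.all(fg == imaging.foreground_intensity)

    def test_noise_deterministic_given_seed(self):
        scene, imaging = single_sphere_setup(background_noise_sd=5.0)
        a = render_stack(scene, imaging, noise_seed=9)
        b = render_stack(scene, imaging, noise_seed=9)
        np.testing.assert_array_equal(a.voxels, b.voxels)
        c = render_stack(scene, imaging, noise_seed=10)
        assert not np.array_equal(a.voxels, c.voxels)

    def test_voxel_count_converges_to_sphere_volume(self):
        radius = 100.0
        true_volume = 4 / 3 * np.pi * radius**3

        def rel_err(voxel):
            scene, imaging = single_sphere_setup(radius=radius, voxel_xy=voxel, dz=voxel)
            stack = render_stack(scene, imaging)
            count = int((stack.voxels > 0).sum())
            return abs(count * stack.voxel_volume - true_volume) / true_volume

        assert rel_err(5.0) < rel_err(20.0)
        assert rel_err(5.0) < 0.02

    def test_empty_grid_rejected(self):
        scene = generate_block_scene(SceneConfig(capture_prob=0.0, plane_p0=500.0))
        with pytest.raises(ValueError, match="grid empty"):
            render_stack(scene, ImagingConfig(voxel_xy=10.0, field_z=10.0))

    def test_scene_outside_field_rejected(self):
        scene, _ = single_sphere_setup()
        small = ImagingConfig(voxel_xy=10.0, field_x=800.0, field_y=800.0, field_z=500.0)
        with pytest.raises(ValueError, match="protrude"):
            render_stack(scene, small)


class TestPlateSeries:
    def test_all_true(self):
        maps = generate_plate_series(6, 1.0, rng_seed=0)
        assert len(maps) == 6
        assert all(m.as_bool().all() for m in maps)

    def test_all_false(self):
        (m,) = generate_plate_series(1, 0.0, rng_seed=0)
        assert not m.as_bool().any()

    def test_per_well_mean_support(self):
        maps = generate_plate_series(6, 0.8, rng_seed=5)
        means = np.mean([m.values for m in maps], axis=0)
        np.testing.assert_allclose(means * 6, np.round(means * 6), atol=1e-12)

    def test_deterministic(self):
        a = generate_plate_series(3, 0.5, rng_seed=17)
        b = generate_plate_series(3, 0.5, rng_seed=17)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.values, mb.values)

    def test_plate_substreams_independent_of_count(self):
        four = generate_plate_series(4, 0.5, rng_seed=17)
        two = generate_plate_series(2, 0.5, rng_seed=17)
        np.testing.assert_array_equal(four[0].values, two[0].values)
        np.testing.assert_array_equal(four[1].values, two[1].values)

    def test_n_plates_validated(self):
        with pytest.raises(ValueError):
            generate_plate_series(0, 0.5, rng_seed=0)
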