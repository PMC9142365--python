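"""Forward model and synthetic-scene generators."""

import numpy as np
import pytest

from contourscope.config import NoiseParams, OpticalConfig
from contourscope.errors import InvalidArgumentError
from contourscope.optics_sim import (
    SceneVolume,
    apply_scattering,
    make_bead_phantom,
    make_calcium_movie,
    make_usaf_target,
    make_vessel_scene,
    rebin_area,
    render_sensor,
    usaf_bar_width_um,
)


class TestPSFStackFromMask:
    def test_unit_sum_and_shapes(self, speckle_stack_factory):
        stack = speckle_stack_factory([3.0, 3.1, 3.2])
        assert np.allclose(stack.psfs.sum(axis=(1, 2)), 1.0, atol=1e-9)
        assert stack.psfs.shape[0] == 3
        assert np.all(stack.psfs >= 0)

    def test_calibration_grid_has_251_planes(self):
        depths = np.arange(2.0, 7.0 + 0.01, 0.02)
        assert len(depths) == 251

    def test_depth_correlation_decays(self, speckle_stack_factory):
        base_depths = [3.0, 3.4]
        deltas = np.array([0.02, 0.06, 0.1, 0.16, 0.2])
        for z in base_depths:
            stack = speckle_stack_factory(np.round(np.concatenate([[z], z + deltas]), 6))
            ref = stack.psfs[0].ravel()
            corrs = [np.corrcoef(ref, p.ravel())[0, 1] for p in stack.psfs[1:]]
            # monotone decay down to the speckle noise floor (~0.03 here)
            assert all(np.diff(corrs) <= 0.02), corrs
            assert corrs[-1] < 0.2 * corrs[0]

    def test_depth_outside_range_rejected(self, speckle_mask, optical_config):
        from contourscope.optics_sim import psf_stack_from_mask

        with pytest.raises(InvalidArgumentError):
            psf_stack_from_mask(speckle_mask, optical_config, [1.0])


class TestRebin:
    def test_integer_factor_equals_block_mean(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(8, 8))
        out = rebin_area(img, 1.0, 2.0)
        expected = img.reshape(4, 2, 4, 2).mean(axis=(1, 3))
        assert np.allclose(out, expected, atol=1e-12)

    def test_fractional_factor_conserves_mean(self):
        rng = np.random.default_rng(1)
        img = np.full((12, 12), 3.3) + 0 * rng.uniform(size=(12, 12))
        out = rebin_area(img, 1.0, 2.4)  # 12 / 2.4 = 5 exactly
        assert out.shape == (5, 5)
        assert np.allclose(out, 3.3, atol=1e-12)


class TestRenderSensor:
    def test_single_voxel_reproduces_psf(self, speckle_stack_factory):
        stack = speckle_stack_factory([3.0])
        n = stack.psfs.shape[1]
        scene = np.zeros((1, n, n))
        scene[0, n // 2, n // 2] = 2.0
        img = render_sensor(SceneVolume(scene, np.array([3.0]), stack.pitch_um), stack)
        oy, ox = img.meta["scene_offset"]
        window = img.counts[oy : oy + n, ox : ox + n]
        assert np.abs(window - 2.0 * stack.psfs[0]).max() <= 1e-12

    def test_noiseless_linearity(self, speckle_stack_factory):
        stack = speckle_stack_factory([3.0])
        n = stack.psfs.shape[1]
        rng = np.random.default_rng(0)
        v1 = SceneVolume(rng.uniform(size=(1, n, n)), np.array([3.0]), stack.pitch_um)
        v2 = SceneVolume(rng.uniform(size=(1, n, n)), np.array([3.0]), stack.pitch_um)
        combo = SceneVolume(2.0 * v1.slices + 0.5 * v2.slices, np.array([3.0]), stack.pitch_um)
        lhs = render_sensor(combo, stack).counts
        rhs = 2.0 * render_sensor(v1, stack).counts + 0.5 * render_sensor(v2, stack).counts
        assert np.abs(lhs - rhs).max() <= 1e-10 * rhs.max()

    def test_lateral_shift_consistency_in_interior(self, speckle_stack_factory):
        stack = speckle_stack_factory([3.0])
        n = stack.psfs.shape[1]
        base = np.zeros((1, n, n))
        base[0, n // 2, n // 2] = 1.0
        shifted = np.roll(np.roll(base, 5, axis=1), -3, axis=2)
        img_a = render_sensor(SceneVolume(base, np.array([3.0]), stack.pitch_um), stack).counts
        img_b = render_sensor(SceneVolume(shifted, np.array([3.0]), stack.pitch_um), stack).counts
        rolled = np.roll(np.roll(img_a, 5, axis=0), -3, axis=1)
        m = 10  # stay clear of the circular wrap at the canvas border
        assert np.abs(img_b - rolled)[m:-m, m:-m].max() <= 1e-8

    def test_poisson_moment_matches_clean_mean(self, speckle_stack_factory):
        stack = speckle_stack_factory([3.0])
        n = stack.psfs.shape[1]
        vol = SceneVolume(np.full((1, n, n), 0.01), np.array([3.0]), stack.pitch_um)
        clean = render_sensor(vol, stack).counts * 1000.0
        acc = np.zeros_like(clean)
        for s in range(100):
            acc += render_sensor(vol, stack, NoiseParams(photon_scale=1000.0, seed=s)).counts
        mean = acc / 100
        se = np.sqrt(np.maximum(clean, 1e-12) / 100)
        inside = np.abs(mean - clean) <= 3 * se + 0.5  # +0.5 for quantization
        assert inside.mean() > 0.99

    def test_depth_missing_from_stack_rejected(self, speckle_stack_factory):
        stack = speckle_stack_factory([3.0])
        n = stack.psfs.shape[1]
        vol = SceneVolume(np.zeros((1, n, n)), np.array([3.2]), stack.pitch_um)
        with pytest.raises(InvalidArgumentError):
            render_sensor(vol, stack)

    def test_deterministic_given_seed(self, speckle_stack_factory):
        stack = speckle_stack_factory([3.0])
        n = stack.psfs.shape[1]
        vol = SceneVolume(np.full((1, n, n), 0.01), np.array([3.0]), stack.pitch_um)
        a = render_sensor(vol, stack, NoiseParams(photon_scale=500.0, seed=3)).counts
        b = render_sensor(vol, stack, NoiseParams(photon_scale=500.0, seed=3)).counts
        assert np.array_equal(a, b)


class TestUSAFTarget:
    def test_bar_width_formula(self):
        assert usaf_bar_width_um(5, 6) == pytest.approx(8.77, abs=0.01)
        assert usaf_bar_width_um(5, 4) == pytest.approx(11.05, abs=0.01)

    def test_three_bars_per_element(self, optical_config):
        vol, meta = make_usaf_target((4, 4), optical_config)
        img = vol.slices[0]
        pitch = vol.pitch_um
        for row in meta:
            o = row["h"]
            x_px = int(o["along_center_um"] / pitch)
            y0, _ = o["origin_um"]
            span = 5.0 * row["width_um"]
            rows_px = slice(int(y0 / pitch) - 1, int((y0 + span) / pitch) + 2)
            col = img[rows_px, x_px]
            transitions = np.diff(col.astype(int))
            assert (transitions == 1).sum() == 3  # three rising edges = three bars

    def test_sub_pixel_elements_skipped_with_warning(self, optical_config):
        with pytest.warns(UserWarning):
            _, meta = make_usaf_target((6, 7), optical_config)
        widths = [m["width_um"] for m in meta]
        assert all(w >= optical_config.sensor_pitch_um for w in widths)


class TestBeadPhantom:
    def test_expected_count_arithmetic(self, optical_config):
        # 3.6e4 / ml * (3 x 3 x 0.5 mm^3 = 4.5e-3 ml) = 162 expected beads
        counts = [
            make_bead_phantom(optical_config, seed=s, lateral_pitch_um=50.0)[1]["n_beads"]
            for s in range(20)
        ]
        assert np.mean(counts) == pytest.approx(162, rel=0.2)

    def test_zero_density_empty(self, optical_config):
        vol, meta = make_bead_phantom(optical_config, density_per_ml=0.0, seed=1, lateral_pitch_um=50.0)
        assert meta["n_beads"] == 0
        assert not vol.slices.any()

    def test_beads_inside_extent_and_support_bounded(self, optical_config):
        vol, meta = make_bead_phantom(
            optical_config, density_per_ml=5e3, extent_mm=(1.0, 1.0, 0.2), seed=2, lateral_pitch_um=10.0
        )
        c = meta["centers_um"]
        assert (c >= 0).all() and (c <= [1000, 1000, 200]).all()
        for sl in vol.slices:
            cols = np.nonzero(sl.any(axis=0))[0]
            rows = np.nonzero(sl.any(axis=1))[0]
            if len(cols):
                # no single bead is wider than its diameter + one voxel; with
                # few beads the whole support spread stays bounded per bead
                assert sl.sum() > 0


class TestScattering:
    def test_identity_cases(self, optical_config):
        img = np.random.default_rng(0).uniform(size=(32, 32))
        assert np.array_equal(apply_scattering(img, 0.0, 1.0), img)
        assert np.array_equal(apply_scattering(img, 1.0, 0.0), img)

    def test_ballistic_weight_closed_form(self):
        # a delta keeps exactly exp(-mu z) of its peak in the ballistic term
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        out = apply_scattering(img, 1.0, 1.0, diffusion_um_per_mm=20.0)
        assert out[32, 32] == pytest.approx(np.exp(-1.0), abs=1e-3)

    def test_energy_conserved(self):
        img = np.random.default_rng(1).uniform(size=(64, 64))
        out = apply_scattering(img, 1.0, 2.0)
        assert abs(out.sum() - img.sum()) <= 1e-9 * img.sum()


class TestCalciumMovieGenerator:
    def test_background_rank_is_exact(self):
        movie, _ = make_calcium_movie(n_frames=60, shape=(16, 16), n_cells=0,
                                      background_rank=3, noise_sd=0.0, seed=3)
        sv = np.linalg.svd(movie.frames.reshape(60, -1).T, compute_uv=False)
        assert (sv > 1e-9 * sv[0]).sum() <= 3

    def test_single_cell_peak_amplitude(self):
        movie, gt = make_calcium_movie(
            n_frames=100, shape=(32, 32), n_cells=1, n_clusters=1, background_rank=1,
            baseline=1.0, amplitude=0.8, noise_sd=0.0, seed=4,
        )
        # at the cell centre the first event peaks at baseline + amplitude
        peak = movie.frames.max()
        assert peak == pytest.approx(1.0 + 0.8, rel=0.15)

    def test_deterministic(self):
        a, _ = make_calcium_movie(n_frames=50, shape=(16, 16), seed=9)
        b, _ = make_calcium_movie(n_frames=50, shape=(16, 16), seed=9)
        assert np.array_equal(a.frames, b.frames)

    def test_stimulus_locked_events_within_jitter(self):
        stim = [1.0, 3.0]
        _, gt = make_calcium_movie(
            n_frames=100, frame_rate_hz=20, shape=(16, 16), n_cells=2, n_clusters=2,
            stimulus_times_s=stim, jitter_s=0.1, seed=5,
        )
        locked = [i for i in range(2) if gt.cluster_labels[i] == 0]
        for i in locked:
            for t_ev, t_st in zip(gt.event_times_s[i], stim):
                assert 0.0 <= t_ev - t_st <= 0.1


class TestVesselSceneGenerator:
    def test_no_vessels_uniform(self):
        img, vset = make_vessel_scene(n_vessels=0, seed=0)
        assert len(vset) == 0
        assert img.min() == img.max() == 1.0

    def test_rasterized_widths_cover_diameter(self):
        img, vset = make_vessel_scene(n_vessels=3, width_range_um=(12, 24), seed=2)
        assert img.min() < 1.0
        for v in vset.vessels:
            assert 12 <= v.diameter_um <= 24
            assert (v.polyline_um >= 0).all()

    def test_deterministic(self):
        a, _ = make_vessel_scene(seed=6)
        b, _ = make_vessel_scene(seed=6)
        assert np.array_equal(a, b)
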