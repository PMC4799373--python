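import numpy as np
import pytest

import microwound as mw
from microwound.scene import GapGeometry, tension_trajectory

from conftest import small_scene_config


class TestGapAreaTrajectory:
    def test_pure_decline_closed_form(self):
        cfg = small_scene_config(
            initial_gap_area=30_000.0, widening_fraction=0.0, closure_rate=1_250.0,
            duration=24.0, frame_interval=0.5, image_shape=(512, 512), band_width=480.0,
        )
        a = mw.gap_area_trajectory(cfg)
        t = cfg.times
        assert a[0] == 30_000.0
        assert a[t == 10.0][0] == pytest.approx(17_500.0)
        assert a[t == 24.0][0] == pytest.approx(0.0)

    def test_affine_until_clip_without_widening(self):
        cfg = small_scene_config(widening_fraction=0.0)
        a = mw.gap_area_trajectory(cfg)
        open_diffs = np.diff(a[a > 0])
        assert np.allclose(open_diffs, -cfg.closure_rate * cfg.frame_interval)

    def test_widening_peak_closed_form(self):
        cfg = small_scene_config(
            initial_gap_area=10_000.0, widening_fraction=0.2, widening_duration=1.0
        )
        a = mw.gap_area_trajectory(cfg)
        assert a[cfg.times == 1.0][0] == pytest.approx(12_000.0)
        assert a.max() == pytest.approx(12_000.0)

    def test_never_negative(self):
        cfg = small_scene_config(closure_rate=5_000.0)
        assert mw.gap_area_trajectory(cfg).min() == 0.0


class TestCellTracks:
    def test_single_edge_cell_steps_tangential(self):
        cfg = small_scene_config(
            n_cells=1, edge_fraction=1.0, tangential_speed=10.0, speed_noise_sd=0.0, seed=3
        )
        geom = GapGeometry(cfg, np.random.default_rng(0))
        tracks, classes = mw.sample_cell_tracks(cfg, geom, np.random.default_rng(1))
        assert classes.tolist() == ["edge"]
        c = geom.center
        for f in range(cfg.n_frames - 1):
            step = tracks[0, f + 1] - tracks[0, f]
            radial = tracks[0, f] - c
            assert np.hypot(*step) == pytest.approx(10.0 * cfg.frame_interval, rel=1e-9)
            assert abs(np.dot(step, radial) / np.hypot(*radial)) < 1e-9

    def test_single_distal_cell_moves_radially_inward(self):
        cfg = small_scene_config(
            n_cells=1, edge_fraction=0.0, radial_speed=5.0, speed_noise_sd=0.0, seed=3
        )
        geom = GapGeometry(cfg, np.random.default_rng(0))
        tracks, classes = mw.sample_cell_tracks(cfg, geom, np.random.default_rng(1))
        assert classes.tolist() == ["distal"]
        net = tracks[0, -1] - tracks[0, 0]
        toward = geom.center - tracks[0, 0]
        cosang = np.dot(net, toward) / (np.hypot(*net) * np.hypot(*toward))
        assert cosang == pytest.approx(1.0, abs=1e-9)

    def test_seeded_tracks_reproducible(self):
        cfg = small_scene_config(n_cells=40, noise_sd=0.0, seed=9)
        geom = GapGeometry(cfg, np.random.default_rng(0))
        t1, _ = mw.sample_cell_tracks(cfg, geom, np.random.default_rng(5))
        t2, _ = mw.sample_cell_tracks(cfg, geom, np.random.default_rng(5))
        assert np.array_equal(t1, t2)

    def test_zero_cells_rejected(self):
        cfg = small_scene_config()
        geom = GapGeometry(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError):
            mw.sample_cell_tracks(cfg, geom, np.random.default_rng(0))

    def test_exclusion_keeps_cells_apart(self):
        cfg = small_scene_config(n_cells=60, edge_fraction=0.3, seed=4)
        geom = GapGeometry(cfg, np.random.default_rng(0))
        tracks, _ = mw.sample_cell_tracks(cfg, geom, np.random.default_rng(2))
        from scipy.spatial.distance import pdist

        for f in range(0, cfg.n_frames, 8):
            assert pdist(tracks[:, f]).min() > 0.6 * cfg.exclusion_distance


class TestBeadsAndTension:
    def test_unit_deflection_closed_form(self):
        cfg = small_scene_config()
        tension = np.full(5, 2.67)
        pos, rest, cant = mw.bead_positions_from_tension(tension, cfg)
        disp = pos - rest[:, None, :]
        assert np.allclose(np.abs(disp[:, :, 0]), 0.5)
        assert np.allclose(disp[:, :, 1], 0.0)
        # cantilever 0 (left) moves +x toward the midline, cantilever 1 -x
        assert np.all(disp[cant == 0, :, 0] > 0)
        assert np.all(disp[cant == 1, :, 0] < 0)

    def test_zero_tension_beads_at_rest(self):
        cfg = small_scene_config()
        pos, rest, _ = mw.bead_positions_from_tension(np.zeros(3), cfg)
        assert np.allclose(pos, rest[:, None, :])

    def test_displacement_linear_in_tension(self):
        cfg = small_scene_config()
        rng = np.random.default_rng(0)
        from microwound.scene import _seed_bead_rest_positions

        rest, cant = _seed_bead_rest_positions(cfg, rng)
        p1, _, _ = mw.bead_positions_from_tension(np.ones(4) * 3.0, cfg, rest, cant)
        p2, _, _ = mw.bead_positions_from_tension(np.ones(4) * 6.0, cfg, rest, cant)
        assert np.allclose(p2 - rest[:, None, :], 2 * (p1 - rest[:, None, :]))

    def test_negative_tension_rejected(self):
        cfg = small_scene_config()
        with pytest.raises(ValueError):
            mw.bead_positions_from_tension(np.array([-1.0]), cfg)

    def test_tension_profile_shape(self):
        prof = mw.TensionProfile()
        t = np.arange(49) * 0.5
        f = tension_trajectory(prof, t)
        assert f[0] == prof.baseline
        assert f[1] == prof.post_minimum
        assert np.argmin(f) == 1
        assert f[t == prof.peak_time][0] == pytest.approx(prof.peak)
        assert f[-1] == pytest.approx(prof.plateau)


class TestRenderScene:
    def test_ground_truth_matches_analytic_trajectory(self, small_noiseless_scene):
        cfg, scene = small_noiseless_scene
        assert np.array_equal(scene.ground_truth.gap_area, mw.gap_area_trajectory(cfg))

    def test_bead_displacement_times_2k_reproduces_tension(self, small_noiseless_scene):
        cfg, scene = small_noiseless_scene
        gt = scene.ground_truth
        disp = np.abs(gt.bead_positions[:, :, 0] - gt.bead_rest[:, None, 0])
        for c in (0, 1):
            defl = disp[gt.bead_cantilever == c].mean(axis=0)
            assert np.allclose(2 * cfg.spring_constant * defl, gt.tension)

    def test_rasterized_gap_area_matches_analytic(self, small_noiseless_scene):
        cfg, scene = small_noiseless_scene
        gt = scene.ground_truth
        params = mw.SegmentationParams(
            threshold_method="fixed", fixed_threshold=0.45, min_region_area=0, closing_radius=0
        )
        px2 = cfg.pixel_size**2
        checked = 0
        for f in range(cfg.n_frames):
            if gt.gap_area[f] / px2 < 500:
                continue
            mask = mw.segment_frame(scene.tissue.frames[f], params)
            pixels, _ = mw.extract_gap_region(mask)
            assert pixels.shape[0] * px2 == pytest.approx(gt.gap_area[f], rel=0.02)
            checked += 1
        assert checked > 5

    def test_noiseless_tissue_channel_two_levels_plus_antialiasing(self, small_noiseless_scene):
        cfg, scene = small_noiseless_scene
        frame = scene.tissue.frames[0]
        levels = np.unique(frame)
        assert levels.min() == np.float32(cfg.background_level)
        assert levels.max() == np.float32(cfg.tissue_level)
        # bulk pixels sit at the two levels; the rest are boundary ramp values
        bulk = np.isin(frame, [np.float32(cfg.background_level), np.float32(cfg.tissue_level)])
        assert bulk.mean() > 0.95

    def test_same_seed_bit_identical(self):
        cfg_a = small_scene_config(n_cells=20, noise_sd=0.05, seed=7)
        cfg_b = small_scene_config(n_cells=20, noise_sd=0.05, seed=7)
        sa, sb = mw.render_scene(cfg_a), mw.render_scene(cfg_b)
        for ch in ("tissue", "nuclei", "beads"):
            assert np.array_equal(getattr(sa, ch).frames, getattr(sb, ch).frames)
        assert np.array_equal(sa.ground_truth.cell_tracks, sb.ground_truth.cell_tracks)

    def test_oversized_gap_rejected(self):
        with pytest.raises(ValueError, match="larger than tissue band"):
            mw.render_scene(small_scene_config(initial_gap_area=120_000.0))

    def test_ground_truth_csvs(self, small_noiseless_scene, tmp_path):
        _, scene = small_noiseless_scene
        paths = scene.ground_truth.to_csvs(tmp_path)
        import pandas as pd

        areas = pd.read_csv(paths["areas"])
        assert list(areas.columns[:2]) == ["t_h", "gap_area_um2"]
        assert len(areas) == scene.tissue.n_frames

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = small_scene_config(n_cells=12, seed=31)
        cfg.to_yaml(tmp_path / "scene.yaml")
        back = mw.SceneConfig.from_yaml(tmp_path / "scene.yaml")
        assert back == cfg
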