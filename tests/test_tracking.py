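import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import microwound as mw
from microwound.scene import render_spots
from microwound.tracking import Track, migration_stats

from conftest import link_identity_accuracy


def make_track(xy, frame_interval=0.5, track_id=0):
    xy = np.asarray(xy, dtype=float)
    frames = np.arange(len(xy))
    return Track(track_id=track_id, frames=frames, t=frames * frame_interval, xy=xy)


def circle_boundary(center, radius, n=360):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.asarray(center) + radius * np.column_stack([np.cos(th), np.sin(th)])


class TestDetectNuclei:
    def test_blank_frame_no_spots(self):
        pos, _ = mw.detect_nuclei(np.zeros((64, 64)), 1.0, blob_sigma=2.0)
        assert pos.shape == (0, 2)

    def test_rendered_spots_recovered_within_one_pixel(self):
        rng = np.random.default_rng(3)
        px = 1.6
        truth = np.column_stack([rng.uniform(30, 370, 20), rng.uniform(30, 370, 20)])
        # enforce generous separation
        keep = [0]
        for i in range(1, 20):
            if min(np.hypot(*(truth[i] - truth[j])) for j in keep) > 25:
                keep.append(i)
        truth = truth[keep]
        img = render_spots((256, 256), truth, px, sigma_um=2.5)
        pos, _ = mw.detect_nuclei(img, px, blob_sigma=2.5, detect_threshold=0.2)
        assert len(pos) == len(truth)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pos).query(truth)
        assert d.max() < px  # within 1 px

    def test_close_pair_merged(self):
        px = 1.0
        sigma = 4.0
        pts = np.array([[50.0, 50.0], [50.0 + 0.5 * sigma, 50.0]])
        img = render_spots((100, 100), pts, px, sigma_um=sigma)
        pos, _ = mw.detect_nuclei(img, px, blob_sigma=sigma, detect_threshold=0.1)
        assert len(pos) == 1

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            mw.detect_nuclei(np.zeros((16, 16)), 1.0, blob_sigma=0.0)


class TestLinkTracks:
    def test_stationary_spots_one_full_track_each(self):
        spots = [np.array([[10.0, 10.0], [40.0, 40.0]])] * 6
        ts = mw.link_tracks(spots, max_link_distance=5.0, frame_interval=0.5)
        assert len(ts) == 2
        assert all(tr.n_samples == 6 for tr in ts.tracks)

    def test_vanishing_spot_terminates_track(self):
        spots = [np.array([[10.0, 10.0], [40.0, 40.0]])] * 3 + [np.array([[40.0, 40.0]])] * 3
        ts = mw.link_tracks(spots, max_link_distance=5.0, frame_interval=0.5)
        lengths = sorted(tr.n_samples for tr in ts.tracks)
        assert lengths == [3, 6]

    def test_no_link_beyond_max_distance(self):
        spots = [np.array([[10.0, 10.0]]), np.array([[40.0, 10.0]])]
        ts = mw.link_tracks(spots, max_link_distance=5.0, frame_interval=0.5)
        assert sorted(tr.n_samples for tr in ts.tracks) == [1, 1]

    def test_no_spot_in_two_tracks(self, default_spots):
        ts = mw.link_tracks(default_spots, 20.0, 0.5)
        total_samples = sum(tr.n_samples for tr in ts.tracks)
        assert total_samples == sum(len(s) for s in default_spots)

    def test_link_identity_accuracy_on_synthetic_scene(self, default_scene, default_spots):
        ts = mw.link_tracks(default_spots, 20.0, 0.5)
        acc = link_identity_accuracy(ts, default_spots, default_scene.ground_truth.cell_tracks)
        assert acc >= 0.95


class TestMigrationStats:
    CENTER = np.array([100.0, 100.0])

    def annotate(self, xy):
        track = make_track(xy)
        centroids = np.tile(self.CENTER, (len(xy), 1))
        boundaries = [circle_boundary(self.CENTER, 20.0)] * len(xy)
        return migration_stats(track, centroids, boundaries, edge_band=25.0, distal_distance=100.0)

    def test_displacement_toward_centroid_is_zero_deg(self):
        tr = self.annotate([[160.0, 100.0], [150.0, 100.0], [140.0, 100.0]])
        assert tr.radial_angle == pytest.approx(0.0, abs=1e-9)

    def test_tangential_displacement_is_ninety_deg(self):
        tr = self.annotate([[160.0, 100.0], [160.0, 105.0], [160.0, 110.0]])
        assert tr.radial_angle == pytest.approx(90.0, abs=1e-9)

    def test_diagonal_displacement_is_45_deg(self):
        tr = self.annotate([[160.0, 100.0], [150.0, 110.0]])
        assert tr.radial_angle == pytest.approx(45.0, abs=1e-9)

    def test_away_from_centroid_is_180_deg(self):
        tr = self.annotate([[160.0, 100.0], [170.0, 100.0]])
        assert tr.radial_angle == pytest.approx(180.0, abs=1e-9)

    def test_location_classes(self):
        edge = self.annotate([[125.0, 100.0], [125.0, 101.0]])  # 5 μm from boundary
        assert edge.location_class == "edge"
        distal = self.annotate([[240.0, 100.0], [240.0, 101.0]])  # 120 μm out
        assert distal.location_class == "distal"
        mid = self.annotate([[160.0, 100.0], [160.0, 101.0]])  # 40 μm out
        assert mid.location_class == "other"

    def test_max_speed(self):
        tr = self.annotate([[160.0, 100.0], [163.0, 104.0], [163.0, 104.0]])
        assert tr.max_speed == pytest.approx(5.0 / 0.5)

    def test_zero_length_interval_rejected(self):
        track = make_track([[0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            migration_stats(track, np.zeros((2, 2)), [None, None], interval=(1.0, 1.0))

    @given(
        angle=st.floats(0, 2 * math.pi),
        start=st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
        disp=st.tuples(st.floats(-20, 20), st.floats(-20, 20)),
    )
    def test_radial_angle_invariant_under_rotation(self, angle, start, disp):
        start = np.asarray(start)
        disp = np.asarray(disp)
        center = np.array([200.0, 200.0])
        if np.hypot(*disp) < 1e-3 or np.hypot(*(center - start)) < 1e-3:
            return
        rot = np.array([[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]])

        def measure(p0, d, c):
            track = make_track([p0, p0 + d])
            return migration_stats(track, np.tile(c, (2, 1)), [None, None]).radial_angle

        a0 = measure(start, disp, center)
        a1 = measure(rot @ start, rot @ disp, rot @ center)
        assert a1 == pytest.approx(a0, abs=1e-6)


class TestWindroseAndSpeeds:
    def build_trackset(self, angles, classes=None):
        tracks = []
        for i, ang in enumerate(angles):
            tr = make_track([[0.0, 0.0], [1.0, 0.0]], track_id=i)
            tr.radial_angle = ang
            tr.location_class = classes[i] if classes else "edge"
            tracks.append(tr)
        return mw.TrackSet(tracks, 20.0, 0.5)

    def test_two_tracks_split_between_bins(self):
        hist = mw.windrose(self.build_trackset([10.0, 80.0]), bin_width_deg=30.0)
        assert hist["percent"].tolist() == [50.0, 0.0, 50.0, 0.0, 0.0, 0.0]

    @given(st.lists(st.floats(0, 180), min_size=1, max_size=40))
    def test_percentages_sum_to_100(self, angles):
        hist = mw.windrose(self.build_trackset(angles), bin_width_deg=20.0)
        assert hist["percent"].sum() == pytest.approx(100.0, abs=0.01)

    def test_class_filter_and_empty_error(self):
        ts = self.build_trackset([10.0, 90.0], classes=["edge", "distal"])
        hist = mw.windrose(ts, 20.0, class_filter="distal")
        assert hist["percent"][hist["bin_start_deg"] == 80.0].iloc[0] == 100.0
        with pytest.raises(ValueError):
            mw.windrose(ts, 20.0, class_filter="other")

    def test_speed_table_stationary_zero(self):
        spots = [np.array([[10.0, 10.0], [40.0, 40.0]])] * 4
        ts = mw.link_tracks(spots, 5.0, 0.5)
        for tr in ts.tracks:
            migration_stats(tr, np.tile([25.0, 25.0], (4, 1)), [None] * 4)
        table = mw.speed_table(ts)
        assert (table["max_speed_um_h"] == 0.0).all()

    def test_edge_cells_tangential_speed_recovered(self):
        """A lone noiseless edge cell's max frame-to-frame speed equals the
        generative tangential speed."""
        from conftest import small_scene_config
        from microwound.scene import GapGeometry

        cfg = small_scene_config(
            n_cells=1, edge_fraction=1.0, tangential_speed=12.0, speed_noise_sd=0.0, seed=6
        )
        geom = GapGeometry(cfg, np.random.default_rng(0))
        tracks, _ = mw.sample_cell_tracks(cfg, geom, np.random.default_rng(1))
        tr = make_track(tracks[0], frame_interval=cfg.frame_interval)
        migration_stats(tr, np.tile(geom.center, (cfg.n_frames, 1)), [None] * cfg.n_frames)
        assert tr.max_speed == pytest.approx(12.0, rel=0.01)
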