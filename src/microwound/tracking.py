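"""Nuclear spot detection, track linking and migration directionality.

Angle convention (radial migration angle): 0° means net displacement toward
the gap centroid, 90° tangential motion along the wound circumference, and
the angle is folded to [0, 180]° (180° = directly away from the gap).
Cells are classed by their mean distance to the wound boundary: within
``edge_band`` of it they are "edge", beyond ``distal_distance`` "distal",
otherwise "other".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.measure import find_contours

from .io import FrameStack
from .morphometrics import MorphometricsSeries

__all__ = [
    "Track",
    "TrackSet",
    "detect_nuclei",
    "detect_nuclei_stack",
    "link_tracks",
    "migration_stats",
    "annotate_tracks",
    "windrose",
    "speed_table",
    "boundaries_from_series",
]


@dataclass
class Track:
    """One linked nuclear trajectory with its migration statistics."""

    track_id: int
    frames: np.ndarray            # consecutive frame indices
    t: np.ndarray                 # hours
    xy: np.ndarray                # (n, 2) μm
    location_class: str = ""
    net_displacement: np.ndarray | None = None   # (dx, dy) μm over the analysis interval
    radial_angle: float = math.nan               # degrees in [0, 180]
    max_speed: float = math.nan                  # μm h⁻¹
    mean_boundary_distance: float = math.nan     # μm

    @property
    def n_samples(self) -> int:
        return len(self.frames)


@dataclass
class TrackSet:
    tracks: list[Track]
    max_link_distance: float
    frame_interval: float
    pixel_size: float = 1.0

    def __len__(self) -> int:
        return len(self.tracks)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for tr in self.tracks:
            for t, (x, y) in zip(tr.t, tr.xy):
                rows.append((tr.track_id, t, x, y))
        return pd.DataFrame(rows, columns=["track_id", "t_h", "x_um", "y_um"])

    def stats_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "track_id": [tr.track_id for tr in self.tracks],
                "class": [tr.location_class for tr in self.tracks],
                "angle_deg": [tr.radial_angle for tr in self.tracks],
                "max_speed_um_h": [tr.max_speed for tr in self.tracks],
                "n_samples": [tr.n_samples for tr in self.tracks],
            }
        )


def detect_nuclei(
    frame: np.ndarray,
    pixel_size: float,
    blob_sigma: float = 3.5,
    detect_threshold: float = 0.2,
):
    """Detect nuclear spots in one frame.

    Scale-normalized Laplacian-of-Gaussian maxima above ``detect_threshold``,
    refined to sub-pixel precision by a local intensity-weighted centroid;
    detections closer than one ``blob_sigma`` (μm) are merged, keeping the
    stronger one.

    Returns ``(positions (N, 2) μm, intensities (N,))``.
    """
    if blob_sigma <= 0:
        raise ValueError("blob_sigma must be > 0")
    img = np.asarray(frame, dtype=float)
    sig = blob_sigma / pixel_size
    resp = -ndi.gaussian_laplace(img, sig) * sig**2
    coords = peak_local_max(
        resp, min_distance=max(1, int(round(sig))), threshold_abs=detect_threshold
    )
    if coords.shape[0] == 0:
        return np.empty((0, 2)), np.empty(0)

    H, W = img.shape
    w = max(2, int(math.ceil(2 * sig)))
    positions = []
    intensities = []
    for r, c in coords:
        r0, r1 = max(0, r - w), min(H, r + w + 1)
        c0, c1 = max(0, c - w), min(W, c + w + 1)
        patch = img[r0:r1, c0:c1]
        weights = np.clip(patch - patch.min(), 0, None)
        tot = weights.sum()
        if tot <= 0:
            positions.append((c, r))
        else:
            rows = np.arange(r0, r1)[:, None]
            cols = np.arange(c0, c1)[None, :]
            positions.append(
                (float((weights * cols).sum() / tot), float((weights * rows).sum() / tot))
            )
        intensities.append(float(resp[r, c]))
    positions = np.asarray(positions) * pixel_size
    intensities = np.asarray(intensities)

    # merge duplicates within one blob_sigma, strongest first
    order = np.argsort(-intensities)
    kept: list[int] = []
    for i in order:
        if all(np.hypot(*(positions[i] - positions[j])) >= blob_sigma for j in kept):
            kept.append(i)
    kept = sorted(kept)
    return positions[kept], intensities[kept]


def detect_nuclei_stack(stack: FrameStack, blob_sigma: float = 3.5, detect_threshold: float = 0.2):
    """Per-frame spot positions (list of (N_i, 2) μm arrays) for a stack."""
    return [
        detect_nuclei(f, stack.pixel_size, blob_sigma, detect_threshold)[0]
        for f in stack.frames
    ]


def link_tracks(
    spots_per_frame: list[np.ndarray],
    max_link_distance: float = 20.0,
    frame_interval: float = 0.5,
    t0: float = 0.0,
) -> TrackSet:
    """Greedy globally-shortest-first frame-to-frame linking.

    Candidate links between consecutive frames are sorted by distance and
    assigned greedily, never exceeding ``max_link_distance`` (μm).  Unmatched
    spots start or terminate tracks; there is no gap closing over missing
    frames.  No spot belongs to two tracks.
    """
    if len(spots_per_frame) < 2:
        raise ValueError("need spots for >= 2 frames")
    tracks_pts: list[list] = []
    tracks_frames: list[list] = []
    prev_track_of_spot: dict[int, int] = {}
    prev_pts = np.asarray(spots_per_frame[0], dtype=float).reshape(-1, 2)
    for j in range(prev_pts.shape[0]):
        prev_track_of_spot[j] = len(tracks_pts)
        tracks_pts.append([prev_pts[j]])
        tracks_frames.append([0])

    for f in range(1, len(spots_per_frame)):
        cur_pts = np.asarray(spots_per_frame[f], dtype=float).reshape(-1, 2)
        cur_track_of_spot: dict[int, int] = {}
        if prev_pts.shape[0] and cur_pts.shape[0]:
            tree_prev = cKDTree(prev_pts)
            tree_cur = cKDTree(cur_pts)
            pairs = tree_prev.sparse_distance_matrix(
                tree_cur, max_link_distance, output_type="coo_matrix"
            )
            order = np.argsort(pairs.data, kind="stable")
            used_prev: set[int] = set()
            used_cur: set[int] = set()
            for k in order:
                i, j = int(pairs.row[k]), int(pairs.col[k])
                if i in used_prev or j in used_cur:
                    continue
                used_prev.add(i)
                used_cur.add(j)
                tid = prev_track_of_spot[i]
                tracks_pts[tid].append(cur_pts[j])
                tracks_frames[tid].append(f)
                cur_track_of_spot[j] = tid
        for j in range(cur_pts.shape[0]):
            if j not in cur_track_of_spot:
                cur_track_of_spot[j] = len(tracks_pts)
                tracks_pts.append([cur_pts[j]])
                tracks_frames.append([f])
        prev_pts = cur_pts
        prev_track_of_spot = cur_track_of_spot

    tracks = [
        Track(
            track_id=i,
            frames=np.asarray(fr, dtype=int),
            t=t0 + np.asarray(fr, dtype=float) * frame_interval,
            xy=np.asarray(pts),
        )
        for i, (fr, pts) in enumerate(zip(tracks_frames, tracks_pts))
    ]
    return TrackSet(tracks, max_link_distance, frame_interval)


def _boundary_for_frame(boundaries, frame: int):
    """Boundary of the given frame, else the nearest open frame's boundary."""
    if boundaries[frame] is not None:
        return boundaries[frame]
    for f in range(frame - 1, -1, -1):
        if boundaries[f] is not None:
            return boundaries[f]
    for f in range(frame + 1, len(boundaries)):
        if boundaries[f] is not None:
            return boundaries[f]
    return None


def migration_stats(
    track: Track,
    centroids: np.ndarray,
    boundaries: list,
    edge_band: float = 25.0,
    distal_distance: float = 100.0,
    interval: tuple[float, float] | None = None,
) -> Track:
    """Annotate a track with net displacement, radial angle, class and speed.

    The radial angle is measured between the net displacement over
    ``interval`` and the unit vector from the cell's start position toward
    the gap centroid (at the start frame), folded to [0, 180]°.  The location
    class uses the track's mean distance to the gap boundary of the same
    frame (falling back to the last open frame's boundary).  Maximum speed is
    the largest consecutive-sample speed over the whole track.
    """
    t = track.t
    if interval is None:
        interval = (float(t[0]), float(t[-1]))
    lo, hi = interval
    if not hi > lo:
        raise ValueError("zero-length interval")
    sel = np.nonzero((t >= lo - 1e-9) & (t <= hi + 1e-9))[0]
    centroids = np.asarray(centroids, dtype=float)

    if sel.size >= 2:
        p_start = track.xy[sel[0]]
        p_end = track.xy[sel[-1]]
        net = p_end - p_start
        track.net_displacement = net
        start_frame = int(track.frames[sel[0]])
        c = centroids[start_frame]
        if np.isnan(c[0]):
            ok = np.nonzero(~np.isnan(centroids[:, 0]))[0]
            if ok.size:
                c = centroids[ok[np.argmin(np.abs(ok - start_frame))]]
        radial = c - p_start
        nr = np.linalg.norm(radial)
        nd = np.linalg.norm(net)
        if nr > 0 and nd > 0:
            cosang = float(np.dot(net, radial) / (nd * nr))
            track.radial_angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))

    dists = []
    for f, p in zip(track.frames, track.xy):
        b = _boundary_for_frame(boundaries, int(f))
        if b is not None:
            dists.append(float(np.min(np.hypot(b[:, 0] - p[0], b[:, 1] - p[1]))))
    if dists:
        mean_d = float(np.mean(dists))
        track.mean_boundary_distance = mean_d
        if mean_d <= edge_band:
            track.location_class = "edge"
        elif mean_d >= distal_distance:
            track.location_class = "distal"
        else:
            track.location_class = "other"

    if track.n_samples >= 2:
        steps = np.diff(track.xy, axis=0)
        dt = np.diff(track.t)
        track.max_speed = float(np.max(np.hypot(steps[:, 0], steps[:, 1]) / dt))
    elif track.n_samples == 1:
        track.max_speed = 0.0
    return track


def boundaries_from_series(series: MorphometricsSeries, n: int = 180) -> list:
    """Per-frame wound-boundary polygons from fitted ellipses (None if closed)."""
    out = []
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    for f in series.frames:
        if f.closed or math.isnan(f.semi_major):
            out.append(None)
            continue
        phi = math.radians(f.orientation_deg if not math.isnan(f.orientation_deg) else 0.0)
        ex = f.semi_major * np.cos(th)
        ey = f.semi_minor * np.sin(th)
        x = f.centroid_x + ex * math.cos(phi) - ey * math.sin(phi)
        y = f.centroid_y + ex * math.sin(phi) + ey * math.cos(phi)
        out.append(np.column_stack([x, y]))
    return out


def annotate_tracks(
    trackset: TrackSet,
    series: MorphometricsSeries | None = None,
    centroids: np.ndarray | None = None,
    boundaries: list | None = None,
    edge_band: float = 25.0,
    distal_distance: float = 100.0,
    interval: tuple[float, float] | None = None,
) -> TrackSet:
    """Annotate every track, taking gap geometry from a morphometrics series
    or from explicit centroid/boundary inputs (e.g. generator ground truth)."""
    if series is not None:
        centroids = series.centroids
        boundaries = boundaries_from_series(series)
    if centroids is None or boundaries is None:
        raise ValueError("provide a morphometrics series or centroids+boundaries")
    for tr in trackset.tracks:
        migration_stats(tr, centroids, boundaries, edge_band, distal_distance, interval)
    return trackset


def windrose(
    trackset: TrackSet,
    bin_width_deg: float = 20.0,
    class_filter: str | None = None,
) -> pd.DataFrame:
    """Angular histogram (% of tracks per radial-angle bin over [0, 180]°).

    Percentages sum to 100 (within rounding).  Raises when no annotated track
    matches the filter.
    """
    if bin_width_deg <= 0:
        raise ValueError("bin_width_deg must be > 0")
    angles = [
        tr.radial_angle
        for tr in trackset.tracks
        if not math.isnan(tr.radial_angle)
        and (class_filter is None or tr.location_class == class_filter)
    ]
    if not angles:
        raise ValueError("no eligible tracks with a defined radial angle")
    edges = np.arange(0.0, 180.0 + bin_width_deg, bin_width_deg)
    if edges[-1] < 180.0:
        edges = np.append(edges, 180.0)
    counts, edges = np.histogram(angles, bins=edges)
    return pd.DataFrame(
        {
            "bin_start_deg": edges[:-1],
            "bin_end_deg": edges[1:],
            "percent": 100.0 * counts / counts.sum(),
        }
    )


def speed_table(trackset: TrackSet, class_filter: str | None = None) -> pd.DataFrame:
    """Per-track maximum frame-to-frame speed table."""
    if not trackset.tracks:
        raise ValueError("empty trackset")
    df = trackset.stats_dataframe().rename(columns={"angle_deg": "radial_angle_deg"})
    if class_filter is not None:
        df = df[df["class"] == class_filter].reset_index(drop=True)
    return df[["track_id", "class", "max_speed_um_h", "n_samples"]]
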