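"""Synthetic wounded-microtissue time-lapse scenes with known ground truth.

The generator emulates the geometry and dynamics the analysis pipeline
assumes: a bright fibrocellular band suspended between two cantilever caps,
an elliptical gap whose area briefly widens and then shrinks linearly at a
constant rate, nuclei that migrate tangentially at the wound edge and
radially inward far from it, and cantilever-cap beads rigidly displaced in
proportion to a prescribed tissue-tension profile (drop right after
wounding, recovery peaking near 10 h, steady plateau slightly below
baseline).

All randomness flows from the single ``SceneConfig.seed``; identical configs
produce bit-identical stacks and ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from .io import FrameStack

__all__ = [
    "TensionProfile",
    "SceneConfig",
    "GroundTruth",
    "SyntheticScene",
    "gap_area_trajectory",
    "tension_trajectory",
    "GapGeometry",
    "sample_cell_tracks",
    "bead_positions_from_tension",
    "render_scene",
]


@dataclass
class TensionProfile:
    """Piecewise-linear total-tension time course (μN).

    Nodes: (t=0, baseline) -> (first post-wound frame, post_minimum)
    -> (peak_time, peak) -> (end, plateau).  The shape mirrors the measured
    response of wounded microtissues: tension collapses immediately after
    the incision, recovers to a contraction peak around 10 h, and settles
    slightly below the pre-wound baseline.
    """

    baseline: float = 12.0
    post_minimum: float = 6.0
    peak: float = 16.0
    peak_time: float = 10.0
    plateau: float = 11.0


@dataclass
class SceneConfig:
    """Full parameterization of a synthetic scene.

    Geometry/calibration defaults correspond to a 10x EMCCD field of view
    (512 px at 1.6 μm/px) imaged every 30 min for 24 h; gap dynamics default
    to the reported mean closure rate of 1,344 μm² h⁻¹ from an initial gap
    of 30,000 μm².  Distances in μm, times in hours, tension in μN.
    """

    image_shape: tuple[int, int] = (512, 512)   # (H, W) px
    pixel_size: float = 1.6                     # μm / px
    frame_interval: float = 0.5                 # h
    duration: float = 24.0                      # h
    # gap dynamics
    gap_center: tuple[float, float] | None = None  # (x, y) μm; None = image center
    initial_gap_area: float = 30_000.0          # μm²
    widening_fraction: float = 0.2              # peak area = (1+f) * initial
    widening_duration: float = 1.0              # h
    closure_rate: float = 1_344.0               # μm² h⁻¹
    gap_aspect_ratio: float = 1.5               # major/minor, >= 1
    roughness_amplitude: float = 0.08           # initial radial roughness, fraction of radius
    # cells
    n_cells: int = 200
    edge_fraction: float = 0.25                 # fraction of cells seeded at the wound edge
    edge_band_width: float = 25.0               # μm
    distal_distance: float = 100.0              # μm from the wound edge
    tangential_speed: float = 10.0              # μm h⁻¹
    radial_speed: float = 5.0                   # μm h⁻¹
    speed_noise_sd: float = 2.0                 # μm h⁻¹ (per coordinate)
    min_cell_spacing: float = 12.0              # μm at seeding
    exclusion_distance: float = 12.0            # μm soft-core nuclear exclusion (0 = off)
    # cantilevers / beads
    n_beads_per_cantilever: int = 4
    n_cantilevers: int = 2
    spring_constant: float = 2.67               # μN μm⁻¹
    tension: TensionProfile = field(default_factory=TensionProfile)
    min_bead_spacing: float = 16.0              # μm
    # rendering
    tissue_level: float = 0.8
    background_level: float = 0.1
    noise_sd: float = 0.08                      # additive Gaussian, all channels
    nucleus_sigma: float = 2.5                  # μm (Gaussian spot)
    bead_sigma: float = 2.4                     # μm
    band_width: float = 480.0                   # μm, vertical extent of the tissue band
    cap_width: float = 50.0                     # μm
    cap_margin: float = 10.0                    # μm from image edge to outer cap face
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.tension, dict):
            self.tension = TensionProfile(**self.tension)
        self.validate()

    def validate(self) -> None:
        if self.closure_rate <= 0:
            raise ValueError("closure_rate must be > 0")
        if self.widening_fraction < 0:
            raise ValueError("widening_fraction must be >= 0")
        if not (0 < self.tension.peak_time < self.duration):
            raise ValueError("tension peak_time must lie within the duration")
        if self.spring_constant <= 0:
            raise ValueError("spring_constant k must be > 0")
        for name in ("tangential_speed", "radial_speed", "speed_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gap_aspect_ratio < 1:
            raise ValueError("gap_aspect_ratio must be >= 1")
        if self.pixel_size <= 0 or self.frame_interval <= 0 or self.duration <= 0:
            raise ValueError("pixel_size, frame_interval and duration must be > 0")
        if self.initial_gap_area <= 0:
            raise ValueError("initial_gap_area must be > 0")
        if self.n_cantilevers != 2:
            raise ValueError("the two-cantilever assay is the supported scene layout")

    # -- derived geometry ------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration / self.frame_interval + 1e-9)) + 1

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def field_um(self) -> tuple[float, float]:
        h, w = self.image_shape
        return (h * self.pixel_size, w * self.pixel_size)

    @property
    def center_um(self) -> np.ndarray:
        if self.gap_center is not None:
            return np.asarray(self.gap_center, dtype=float)
        h_um, w_um = self.field_um
        return np.array([w_um / 2.0, h_um / 2.0])

    def band_bounds(self) -> tuple[float, float, float, float]:
        """(x0, x1, y0, y1) μm of the tissue band rectangle."""
        h_um, w_um = self.field_um
        cy = h_um / 2.0
        half = self.band_width / 2.0
        return (self.cap_margin, w_um - self.cap_margin, cy - half, cy + half)

    def cap_bounds(self, cantilever: int) -> tuple[float, float, float, float]:
        """(x0, x1, y0, y1) μm of one cantilever cap rectangle."""
        h_um, w_um = self.field_um
        cy = h_um / 2.0
        cap_half = min(self.band_width / 2.0, 120.0)
        if cantilever == 0:
            return (self.cap_margin, self.cap_margin + self.cap_width, cy - cap_half, cy + cap_half)
        return (w_um - self.cap_margin - self.cap_width, w_um - self.cap_margin, cy - cap_half, cy + cap_half)

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        if self.gap_center is not None:
            d["gap_center"] = list(self.gap_center)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        if "image_shape" in d:
            d["image_shape"] = tuple(d["image_shape"])
        if d.get("gap_center") is not None:
            d["gap_center"] = tuple(d["gap_center"])
        if isinstance(d.get("tension"), dict):
            d["tension"] = TensionProfile(**d["tension"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SceneConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path


def gap_area_trajectory(config: SceneConfig) -> np.ndarray:
    """Analytic per-frame gap area (μm²).

    The area rises linearly from ``initial_gap_area`` to
    ``(1 + widening_fraction) * initial_gap_area`` over ``widening_duration``
    hours, then declines linearly at ``closure_rate``, clipped at zero.
    With ``widening_fraction == 0`` the decline starts at t = 0.
    """
    t = config.times
    f = config.widening_fraction
    wd = config.widening_duration if f > 0 else 0.0
    peak = config.initial_gap_area * (1.0 + f)
    if wd > 0:
        rising = config.initial_gap_area * (1.0 + f * t / wd)
        falling = peak - config.closure_rate * (t - wd)
        area = np.where(t <= wd, rising, falling)
    else:
        area = peak - config.closure_rate * t
    return np.clip(area, 0.0, None)


def tension_trajectory(profile: TensionProfile, times: np.ndarray) -> np.ndarray:
    """Piecewise-linear tension series (μN) on the given time grid.

    t <= 0 maps to the pre-wound baseline; the post-wound branch passes
    through (first post-wound time, post_minimum), (peak_time, peak) and
    (last time, plateau).
    """
    times = np.asarray(times, dtype=float)
    post = times[times > 0]
    out = np.full(times.shape, profile.baseline, dtype=float)
    if post.size == 0:
        return out
    t1 = post[0]
    t_end = max(post[-1], profile.peak_time + 1e-9)
    xp = [t1, profile.peak_time, t_end]
    fp = [profile.post_minimum, profile.peak, profile.plateau]
    if not (t1 < profile.peak_time):
        xp, fp = [t1, t_end], [profile.peak, profile.plateau]
    out[times > 0] = np.interp(post, xp, fp)
    return out


class GapGeometry:
    """Per-frame wound-boundary radius R(θ) around a fixed centroid.

    The boundary is an ellipse (major axis along the inter-cantilever x-axis)
    multiplied by a low-order Fourier roughness whose amplitude decays to
    zero over the widening phase — the rough fresh wound edge smoothens into
    an ellipse.  Each frame's boundary is rescaled so that its enclosed area
    equals the analytic gap-area trajectory exactly (to quadrature accuracy).
    """

    N_THETA = 2048
    #: Fourier modes used for edge roughness
    MODES = (3, 4, 5, 6, 7)

    def __init__(self, config: SceneConfig, rng: np.random.Generator):
        self.config = config
        self.center = config.center_um
        self.areas = gap_area_trajectory(config)
        self.theta = np.linspace(0.0, 2 * np.pi, self.N_THETA, endpoint=False)

        alpha = rng.normal(0.0, 1.0, len(self.MODES)) / np.asarray(self.MODES)
        beta = rng.normal(0.0, 1.0, len(self.MODES)) / np.asarray(self.MODES)
        rho = np.zeros_like(self.theta)
        for m, a, b in zip(self.MODES, alpha, beta):
            rho += a * np.cos(m * self.theta) + b * np.sin(m * self.theta)
        peak = np.abs(rho).max()
        self.rho = rho / peak if peak > 0 else rho

        t = config.times
        wd = config.widening_duration
        if config.roughness_amplitude > 0 and wd > 0:
            eps = config.roughness_amplitude * np.clip(1.0 - t / wd, 0.0, 1.0)
        else:
            eps = np.zeros_like(t)
        self.eps = eps

        q = config.gap_aspect_ratio
        radii = np.zeros((config.n_frames, self.N_THETA))
        for i, area in enumerate(self.areas):
            if area <= 0:
                continue
            b0 = math.sqrt(area / (math.pi * q))
            a0 = q * b0
            r0 = a0 * b0 / np.hypot(b0 * np.cos(self.theta), a0 * np.sin(self.theta))
            pert = r0 * (1.0 + eps[i] * self.rho)
            quad_area = math.pi * float(np.mean(pert**2))
            radii[i] = pert * math.sqrt(area / quad_area)
        self.radii = radii

    def radius(self, theta, frame: int):
        """Boundary radius (μm) at polar angle(s) ``theta`` for one frame."""
        theta = np.asarray(theta, dtype=float)
        return np.interp(np.mod(theta, 2 * np.pi), self.theta, self.radii[frame], period=2 * np.pi)

    def nominal_axes(self, frame: int) -> tuple[float, float]:
        """(semi-major, semi-minor) μm of the unperturbed ellipse of equal area."""
        area = self.areas[frame]
        if area <= 0:
            return (float("nan"), float("nan"))
        q = self.config.gap_aspect_ratio
        b = math.sqrt(area / (math.pi * q))
        return (q * b, b)

    def boundary_points(self, frame: int, n: int = 256) -> np.ndarray | None:
        """Sampled boundary polygon (n, 2) in μm, or None for a closed gap."""
        if self.areas[frame] <= 0:
            return None
        th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        r = self.radius(th, frame)
        return self.center + np.column_stack([r * np.cos(th), r * np.sin(th)])

    def max_extent(self) -> tuple[float, float]:
        """Largest |x| and |y| boundary excursion from the centroid over all frames."""
        x = np.abs(self.radii * np.cos(self.theta)).max() if self.radii.size else 0.0
        y = np.abs(self.radii * np.sin(self.theta)).max() if self.radii.size else 0.0
        return float(x), float(y)


# ---------------------------------------------------------------------------
# cells


def _seed_positions(config, geom, rng, n, kind):
    """Rejection-sample non-overlapping initial cell positions of one class."""
    x0, x1, y0, y1 = config.band_bounds()
    margin = 6.0
    accepted: list[np.ndarray] = []
    attempts = 0
    max_attempts = 500 * max(n, 1)
    while len(accepted) < n and attempts < max_attempts:
        attempts += 1
        theta = rng.uniform(0.0, 2 * np.pi)
        if kind == "edge":
            d = rng.uniform(2.0, 0.9 * config.edge_band_width)
        else:
            d = rng.uniform(config.distal_distance + 10.0, config.distal_distance + 60.0)
        r = geom.radius(theta, 0) + d
        p = geom.center + r * np.array([math.cos(theta), math.sin(theta)])
        if not (x0 + margin < p[0] < x1 - margin and y0 + margin < p[1] < y1 - margin):
            continue
        if accepted and np.min(np.linalg.norm(np.asarray(accepted) - p, axis=1)) < config.min_cell_spacing:
            continue
        accepted.append(p)
    if len(accepted) < n:
        raise RuntimeError(
            f"could not place {n} {kind} cells with spacing {config.min_cell_spacing} μm; "
            "reduce n_cells or enlarge the scene"
        )
    return np.asarray(accepted)


def _resolve_overlaps(pos: np.ndarray, d_ex: float, iters: int = 8) -> np.ndarray:
    """Push cell pairs closer than d_ex apart (soft volume exclusion)."""
    for _ in range(iters):
        pairs = cKDTree(pos).query_pairs(d_ex, output_type="ndarray")
        if pairs.shape[0] == 0:
            break
        disp = np.zeros_like(pos)
        for i, j in pairs:
            v = pos[j] - pos[i]
            d = math.hypot(v[0], v[1])
            if d < 1e-6:
                v = np.array([1.0, 0.0])
                d = 1.0
            push = 0.5 * (d_ex - min(d, d_ex)) * v / d
            disp[i] -= push
            disp[j] += push
        pos = pos + disp
    return pos


def sample_cell_tracks(config: SceneConfig, geom: GapGeometry, rng: np.random.Generator):
    """Simulate nuclear trajectories around the closing gap.

    Edge-class cells (seeded within ``edge_band_width`` of the wound
    boundary) take steps of length ``tangential_speed * dt`` exactly
    perpendicular to the local radius from the gap centroid, with a
    per-cell persistent direction sign.  Distal-class cells (seeded at
    >= ``distal_distance`` from the boundary) step radially inward at
    ``radial_speed``.  Isotropic Gaussian positional noise with per-frame
    s.d. ``speed_noise_sd * dt`` is added to every cell.

    Returns
    -------
    tracks : (n_cells, T, 2) array of μm positions
    classes : (n_cells,) array of {"edge", "distal"} labels
    """
    if config.n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    n_edge = int(round(config.n_cells * config.edge_fraction))
    n_distal = config.n_cells - n_edge
    dt = config.frame_interval
    T = config.n_frames
    c = geom.center

    p_edge = _seed_positions(config, geom, rng, n_edge, "edge") if n_edge else np.zeros((0, 2))
    p_dist = _seed_positions(config, geom, rng, n_distal, "distal") if n_distal else np.zeros((0, 2))
    signs = rng.choice([-1.0, 1.0], size=n_edge)

    pos = np.vstack([p_edge, p_dist])
    n = pos.shape[0]
    tracks = np.empty((n, T, 2))
    tracks[:, 0] = pos
    for f in range(1, T):
        u = pos - c
        r = np.linalg.norm(u, axis=1)
        r = np.where(r > 1e-9, r, 1e-9)
        uhat = u / r[:, None]
        step = np.zeros_like(pos)
        if n_edge:
            tang = np.column_stack([-uhat[:n_edge, 1], uhat[:n_edge, 0]]) * signs[:, None]
            step[:n_edge] = config.tangential_speed * dt * tang
        if n_distal:
            inward = -uhat[n_edge:]
            d_step = config.radial_speed * dt
            # do not step into the gap: hold position once at the boundary
            boundary_r = geom.radius(np.arctan2(u[n_edge:, 1], u[n_edge:, 0]), f)
            ok = (r[n_edge:] - d_step) > (boundary_r + 2.0)
            step[n_edge:] = np.where(ok[:, None], d_step * inward, 0.0)
        noise = rng.normal(0.0, config.speed_noise_sd * dt, size=(n, 2))
        pos = pos + step + noise
        if config.exclusion_distance > 0 and n > 1:
            pos = _resolve_overlaps(pos, config.exclusion_distance)
        tracks[:, f] = pos
    classes = np.array(["edge"] * n_edge + ["distal"] * n_distal)
    return tracks, classes


# ---------------------------------------------------------------------------
# beads / tension


def _seed_bead_rest_positions(config: SceneConfig, rng: np.random.Generator):
    """Rest (zero-load) bead positions on the two cap surfaces."""
    h_um, _ = config.field_um
    cy = h_um / 2.0
    rest = []
    cant_ids = []
    for cant in range(2):
        x0, x1, _, _ = config.cap_bounds(cant)
        placed: list[np.ndarray] = []
        attempts = 0
        while len(placed) < config.n_beads_per_cantilever and attempts < 5000:
            attempts += 1
            p = np.array([rng.uniform(x0 + 6.0, x1 - 6.0), rng.uniform(cy - 45.0, cy + 45.0)])
            if placed and np.min(np.linalg.norm(np.asarray(placed) - p, axis=1)) < config.min_bead_spacing:
                continue
            placed.append(p)
        if len(placed) < config.n_beads_per_cantilever:
            raise RuntimeError("could not place beads with the requested spacing")
        rest.extend(placed)
        cant_ids.extend([cant] * config.n_beads_per_cantilever)
    return np.asarray(rest), np.asarray(cant_ids)


def bead_positions_from_tension(
    tension: np.ndarray,
    config: SceneConfig,
    rest_positions: np.ndarray | None = None,
    cantilever_ids: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
):
    """Rigid per-frame bead positions under a given tension series.

    The total tension F splits equally across the two cantilevers, each of
    which deflects by ``F / (2k)`` toward the tissue midline along the
    inter-cantilever (x) axis.  Beads ride rigidly on their cap.

    Returns ``(positions (B, T, 2) μm, rest (B, 2) μm, cantilever_ids (B,))``.
    """
    tension = np.asarray(tension, dtype=float)
    if np.any(tension < 0):
        raise ValueError("tension must be >= 0 everywhere")
    if config.spring_constant <= 0:
        raise ValueError("spring_constant k must be > 0")
    if rest_positions is None:
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        rest_positions, cantilever_ids = _seed_bead_rest_positions(config, rng)
    rest_positions = np.asarray(rest_positions, dtype=float)
    cantilever_ids = np.asarray(cantilever_ids)
    deflection = tension / (2.0 * config.spring_constant)  # per cantilever, μm
    signs = np.where(cantilever_ids == 0, 1.0, -1.0)  # toward the midline
    positions = np.empty((rest_positions.shape[0], tension.size, 2))
    positions[:, :, 0] = rest_positions[:, None, 0] + signs[:, None] * deflection[None, :]
    positions[:, :, 1] = rest_positions[:, None, 1]
    return positions, rest_positions, cantilever_ids


# ---------------------------------------------------------------------------
# rendering


def render_spots(shape, positions_um, pixel_size: float, sigma_um: float, amplitude: float = 1.0):
    """Additively render isotropic Gaussian spots onto a zeroed image."""
    img = np.zeros(shape, dtype=float)
    sig = sigma_um / pixel_size
    w = max(2, int(math.ceil(4 * sig)))
    H, W = shape
    for x_um, y_um in np.atleast_2d(positions_um):
        cx, cy = x_um / pixel_size, y_um / pixel_size
        r0 = max(0, int(round(cy)) - w)
        r1 = min(H, int(round(cy)) + w + 1)
        c0 = max(0, int(round(cx)) - w)
        c1 = min(W, int(round(cx)) + w + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        yy = np.arange(r0, r1)[:, None]
        xx = np.arange(c0, c1)[None, :]
        img[r0:r1, c0:c1] += amplitude * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sig**2))
    return img


def _rect_coverage(coords: np.ndarray, lo: float, hi: float, px: float) -> np.ndarray:
    """1D anti-aliased coverage of the interval [lo, hi] for pixel centers."""
    return np.clip((coords - lo) / px + 0.5, 0, 1) * np.clip((hi - coords) / px + 0.5, 0, 1)


@dataclass
class GroundTruth:
    """Exact generative state mirrored by every measured quantity."""

    times: np.ndarray                 # (T,) h
    gap_area: np.ndarray              # (T,) μm²
    gap_centroid: np.ndarray          # (T, 2) μm
    ellipse_axes: np.ndarray          # (T, 2) (a, b) μm
    cell_tracks: np.ndarray           # (N, T, 2) μm
    cell_classes: np.ndarray          # (N,)
    bead_positions: np.ndarray        # (B, T, 2) μm
    bead_rest: np.ndarray             # (B, 2) μm
    bead_cantilever: np.ndarray       # (B,)
    tension: np.ndarray               # (T,) μN
    geometry: GapGeometry
    config: SceneConfig

    def boundary_points(self, frame: int, n: int = 256):
        return self.geometry.boundary_points(frame, n)

    def to_csvs(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        areas = pd.DataFrame(
            {
                "t_h": self.times,
                "gap_area_um2": self.gap_area,
                "centroid_x_um": self.gap_centroid[:, 0],
                "centroid_y_um": self.gap_centroid[:, 1],
                "a_um": self.ellipse_axes[:, 0],
                "b_um": self.ellipse_axes[:, 1],
            }
        )
        paths["areas"] = outdir / "areas.csv"
        areas.to_csv(paths["areas"], index=False)

        n, T, _ = self.cell_tracks.shape
        tracks = pd.DataFrame(
            {
                "cell_id": np.repeat(np.arange(n), T),
                "class": np.repeat(self.cell_classes, T),
                "t_h": np.tile(self.times, n),
                "x_um": self.cell_tracks[:, :, 0].ravel(),
                "y_um": self.cell_tracks[:, :, 1].ravel(),
            }
        )
        paths["tracks"] = outdir / "tracks.csv"
        tracks.to_csv(paths["tracks"], index=False)

        b = self.bead_positions.shape[0]
        beads = pd.DataFrame(
            {
                "bead_id": np.repeat(np.arange(b), T),
                "cantilever": np.repeat(self.bead_cantilever, T),
                "rest_x_um": np.repeat(self.bead_rest[:, 0], T),
                "rest_y_um": np.repeat(self.bead_rest[:, 1], T),
                "t_h": np.tile(self.times, b),
                "x_um": self.bead_positions[:, :, 0].ravel(),
                "y_um": self.bead_positions[:, :, 1].ravel(),
            }
        )
        paths["beads"] = outdir / "beads.csv"
        beads.to_csv(paths["beads"], index=False)

        tension = pd.DataFrame({"t_h": self.times, "tension_uN": self.tension})
        paths["tension"] = outdir / "tension.csv"
        tension.to_csv(paths["tension"], index=False)
        return paths


@dataclass
class SyntheticScene:
    tissue: FrameStack
    nuclei: FrameStack
    beads: FrameStack
    ground_truth: GroundTruth

    def __iter__(self):
        return iter((self.tissue, self.nuclei, self.beads, self.ground_truth))


def render_scene(config: SceneConfig) -> SyntheticScene:
    """Render the three-channel time-lapse scene plus its ground truth.

    Channels: ``tissue`` (bright band between the caps minus the gap),
    ``nuclei`` (Gaussian spots at cell positions) and ``beads`` (Gaussian
    spots at cantilever-bead positions).  Additive Gaussian noise of s.d.
    ``noise_sd`` is applied to all channels and clipped at zero.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_rough, rng_cells, rng_beads, rng_noise = [np.random.default_rng(s) for s in ss.spawn(4)]

    geom = GapGeometry(config, rng_rough)
    times = config.times
    T = config.n_frames
    H, W = config.image_shape
    px = config.pixel_size

    # gap must fit inside the tissue band between the caps
    max_x, max_y = geom.max_extent()
    x0, x1, y0, y1 = config.band_bounds()
    cx, cy = geom.center
    cap0 = config.cap_bounds(0)
    cap1 = config.cap_bounds(1)
    if (
        cy - max_y < y0 + 2 * px
        or cy + max_y > y1 - 2 * px
        or cx - max_x < cap0[1] + 2 * px
        or cx + max_x > cap1[0] - 2 * px
    ):
        raise ValueError("gap larger than tissue band")

    # static band template (the caps lie within the band rectangle; they are
    # visible in the bead channel, not as a separate tissue intensity level)
    xs = np.arange(W) * px
    ys = np.arange(H) * px
    band = _rect_coverage(ys, y0, y1, px)[:, None] * _rect_coverage(xs, x0, x1, px)[None, :]

    if config.n_cells > 0:
        tracks, classes = sample_cell_tracks(config, geom, rng_cells)
    else:
        tracks = np.zeros((0, config.n_frames, 2))
        classes = np.array([], dtype="<U6")
    tension = tension_trajectory(config.tension, times)
    bead_pos, bead_rest, bead_cant = bead_positions_from_tension(
        tension, config, rng=rng_beads
    )

    tissue_frames = np.empty((T, H, W), dtype=np.float32)
    nuclei_frames = np.empty((T, H, W), dtype=np.float32)
    bead_frames = np.empty((T, H, W), dtype=np.float32)
    bg, lvl = config.background_level, config.tissue_level

    for f in range(T):
        gap_cov = np.zeros((H, W))
        if geom.areas[f] > 0:
            rmax = geom.radii[f].max() + 3 * px
            r0 = max(0, int((cy - rmax) / px) - 1)
            r1 = min(H, int((cy + rmax) / px) + 2)
            c0 = max(0, int((cx - rmax) / px) - 1)
            c1 = min(W, int((cx + rmax) / px) + 2)
            dy = ys[r0:r1, None] - cy
            dx = xs[None, c0:c1] - cx
            rr = np.hypot(dx, dy)
            th = np.arctan2(dy, dx)
            rb = geom.radius(th.ravel(), f).reshape(th.shape)
            gap_cov[r0:r1, c0:c1] = np.clip((rb - rr) / px + 0.5, 0, 1)
        tissue_frames[f] = bg + (lvl - bg) * band * (1.0 - gap_cov)
        nuclei_frames[f] = (
            render_spots((H, W), tracks[:, f], px, config.nucleus_sigma)
            if tracks.shape[0]
            else np.zeros((H, W))
        )
        bead_frames[f] = render_spots((H, W), bead_pos[:, f], px, config.bead_sigma)

    if config.noise_sd > 0:
        for arr in (tissue_frames, nuclei_frames, bead_frames):
            arr += rng_noise.normal(0.0, config.noise_sd, size=arr.shape).astype(np.float32)
    np.clip(tissue_frames, 0, None, out=tissue_frames)
    np.clip(nuclei_frames, 0, None, out=nuclei_frames)
    np.clip(bead_frames, 0, None, out=bead_frames)

    gt = GroundTruth(
        times=times,
        gap_area=geom.areas.copy(),
        gap_centroid=np.tile(geom.center, (T, 1)),
        ellipse_axes=np.array([geom.nominal_axes(f) for f in range(T)]),
        cell_tracks=tracks,
        cell_classes=classes,
        bead_positions=bead_pos,
        bead_rest=bead_rest,
        bead_cantilever=bead_cant,
        tension=tension,
        geometry=geom,
        config=config,
    )
    mk = lambda frames, name: FrameStack(frames, px, config.frame_interval, channel_name=name)
    return SyntheticScene(mk(tissue_frames, "tissue"), mk(nuclei_frames, "nuclei"), mk(bead_frames, "beads"), gt)
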