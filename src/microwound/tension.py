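"""Cantilever-bead tracking and deflection-to-tension conversion.

Total tissue tension is the calibrated spring constant k (μN μm⁻¹) times the
sum of the per-cantilever deflections.  Deflections are measured against the
beads' rest positions (recorded after enzymatic release of the tissue, when
the cantilevers carry no load), so the pre-wound frames already show a
positive baseline tension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FrameStack

__all__ = [
    "BeadTrack",
    "TensionSeries",
    "track_beads",
    "deflections",
    "total_tension",
    "normalize_tension",
]


@dataclass
class BeadTrack:
    """One fluorescent bead followed across a stack."""

    bead_id: int
    cantilever: int
    positions: np.ndarray                  # (T, 2) μm, NaN after loss
    baseline: np.ndarray | None = None     # (2,) μm rest position
    lost: bool = False
    lost_frame: int | None = None


@dataclass
class TensionSeries:
    """Per-frame total tissue tension and the deflections it came from."""

    times: np.ndarray          # (T,) h
    tension: np.ndarray        # (T,) μN
    deflections: np.ndarray    # (T, n_cantilevers) μm
    spring_constant: float     # μN μm⁻¹
    baseline_tension: float    # μN, mean over the pre-wound window

    def normalized(self) -> np.ndarray:
        """Tension divided by the pre-wound baseline (pre-wound maps to ~1)."""
        if not self.baseline_tension > 0:
            raise ValueError("baseline tension must be > 0 to normalize")
        return self.tension / self.baseline_tension

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"t_h": self.times})
        for c in range(self.deflections.shape[1]):
            df[f"deflection_c{c}_um"] = self.deflections[:, c]
        df["tension_uN"] = self.tension
        try:
            df["tension_norm"] = self.normalized()
        except ValueError:
            df["tension_norm"] = np.nan
        return df


def track_beads(
    stack: FrameStack,
    initial_positions: np.ndarray,
    search_radius: float = 8.0,
    cantilever_ids: np.ndarray | None = None,
    min_signal: float = 0.05,
    n_refine: int = 3,
) -> list[BeadTrack]:
    """Follow beads by iterated intensity-weighted centroids.

    Each bead is relocated per frame to the background-subtracted,
    intensity-weighted centroid of a window of half-width ``search_radius``
    (μm) centered on its previous position, re-centered ``n_refine`` times.
    A bead whose window holds no signal above ``min_signal`` over background
    is flagged lost and its later positions are NaN; lost beads are excluded
    from tension computation downstream.

    ``cantilever_ids`` defaults to a left/right split of the initial
    positions about their median x.
    """
    init = np.asarray(initial_positions, dtype=float).reshape(-1, 2)
    if cantilever_ids is None:
        cantilever_ids = (init[:, 0] > np.median(init[:, 0])).astype(int)
    px = stack.pixel_size
    halfw = max(2, int(math.ceil(search_radius / px)))
    T = stack.n_frames
    H, W = stack.frames.shape[1:]
    tracks: list[BeadTrack] = []
    for b, p0 in enumerate(init):
        positions = np.full((T, 2), np.nan)
        pos = p0.copy()
        lost = False
        lost_frame = None
        for f in range(T):
            if lost:
                break
            for _ in range(n_refine):
                cc = pos[0] / px
                cr = pos[1] / px
                r0, r1 = max(0, int(round(cr)) - halfw), min(H, int(round(cr)) + halfw + 1)
                c0, c1 = max(0, int(round(cc)) - halfw), min(W, int(round(cc)) + halfw + 1)
                if r0 >= r1 or c0 >= c1:
                    lost = True
                    break
                win = stack.frames[f, r0:r1, c0:c1].astype(float)
                bg = float(np.median(win))
                w = np.clip(win - bg, 0, None)
                if w.max() < min_signal:
                    lost = True
                    break
                rows = np.arange(r0, r1)[:, None]
                cols = np.arange(c0, c1)[None, :]
                tot = w.sum()
                pos = np.array([(w * cols).sum() / tot * px, (w * rows).sum() / tot * px])
            if lost:
                lost_frame = f
                break
            positions[f] = pos
        tracks.append(
            BeadTrack(
                bead_id=b,
                cantilever=int(cantilever_ids[b]),
                positions=positions,
                lost=lost,
                lost_frame=lost_frame,
            )
        )
    return tracks


def deflections(
    bead_tracks: list[BeadTrack],
    baselines: np.ndarray,
    axis_angle_deg: float = 0.0,
    mode: str = "projected",
    n_cantilevers: int = 2,
) -> np.ndarray:
    """Per-cantilever per-frame deflection (μm) from bead displacements.

    Displacement of each bead from its rest (baseline) position is projected
    onto the inter-cantilever axis, signed toward the tissue midline
    (``mode="projected"``, the default; off-axis jitter is noise, not load),
    or taken as the planar displacement magnitude (``mode="magnitude"``).
    The per-cantilever deflection is the mean over that cantilever's
    non-lost beads; a cantilever with zero valid beads is an error.
    """
    if mode not in ("projected", "magnitude"):
        raise ValueError("mode must be 'projected' or 'magnitude'")
    baselines = np.asarray(baselines, dtype=float).reshape(-1, 2)
    if len(bead_tracks) != baselines.shape[0]:
        raise ValueError("one baseline per bead is required")
    T = bead_tracks[0].positions.shape[0]
    phi = math.radians(axis_angle_deg)
    axis = np.array([math.cos(phi), math.sin(phi)])
    proj_rest = baselines @ axis
    mid = 0.5 * (proj_rest.min() + proj_rest.max())

    sums = np.zeros((T, n_cantilevers))
    counts = np.zeros(n_cantilevers, dtype=int)
    for tr, base in zip(bead_tracks, baselines):
        if tr.lost:
            continue
        if tr.cantilever < 0 or tr.cantilever >= n_cantilevers:
            raise ValueError(f"cantilever id {tr.cantilever} out of range")
        disp = tr.positions - base
        if mode == "projected":
            sign = 1.0 if (base @ axis) < mid else -1.0
            d = sign * (disp @ axis)
        else:
            d = np.hypot(disp[:, 0], disp[:, 1])
        sums[:, tr.cantilever] += d
        counts[tr.cantilever] += 1
    if np.any(counts == 0):
        missing = np.nonzero(counts == 0)[0].tolist()
        raise ValueError(f"cantilever(s) {missing} have no valid beads")
    return sums / counts


def total_tension(
    defl: np.ndarray,
    k: float,
    times: np.ndarray | None = None,
    pre_wound_frames: int = 1,
) -> TensionSeries:
    """Convert per-cantilever deflections to total tension: F(t) = k * Σ_c δ_c(t).

    The baseline tension is the mean tension over the first
    ``pre_wound_frames`` frames (acquired before wounding).
    """
    if k <= 0:
        raise ValueError("spring constant k must be > 0")
    defl = np.asarray(defl, dtype=float)
    if defl.ndim == 1:
        defl = defl[:, None]
    if np.any(np.isnan(defl)):
        raise ValueError("missing frames in the deflection table")
    tension = k * defl.sum(axis=1)
    if times is None:
        times = np.arange(defl.shape[0], dtype=float)
    times = np.asarray(times, dtype=float)
    if times.shape[0] != defl.shape[0]:
        raise ValueError("times and deflections disagree in length")
    pre = max(1, int(pre_wound_frames))
    baseline = float(np.mean(tension[:pre]))
    return TensionSeries(
        times=times,
        tension=tension,
        deflections=defl,
        spring_constant=float(k),
        baseline_tension=baseline,
    )


def normalize_tension(series: TensionSeries) -> np.ndarray:
    """Dimensionless tension relative to the pre-wound baseline."""
    return series.normalized()
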