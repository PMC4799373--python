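"""Per-frame tissue/gap segmentation and shape measurement.

Segmentation follows the brightness-threshold scheme used for microtissue
movies: pixels above a threshold (Otsu per frame by default, or a fixed
value) are tissue; background regions are classified as "around" the tissue
when they touch the image border and as candidate wounds when they are fully
enclosed.  The wound is the largest enclosed hole, with ties broken by
proximity to the previous frame's gap centroid (a tissue carries a single
surgical wound).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, perimeter_crofton, regionprops
from skimage.morphology import closing, disk, remove_small_objects

from .io import FrameStack

__all__ = [
    "SegmentationParams",
    "GapMorphometrics",
    "MorphometricsSeries",
    "segment_frame",
    "extract_gap_region",
    "measure_gap",
    "tissue_width",
    "morphometrics_series",
]

#: default area below which a gap counts as closed (μm²)
DEFAULT_CLOSURE_THRESHOLD = 100.0


@dataclass
class SegmentationParams:
    """Parameters of the brightness-threshold tissue segmentation."""

    threshold_method: str = "otsu"          # "otsu" | "fixed"
    fixed_threshold: float | None = None    # intensity, required for "fixed"
    min_region_area: int = 64               # px, smaller tissue components dropped
    closing_radius: int = 2                 # px, morphological closing of the mask

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.min_region_area < 0 or self.closing_radius < 0:
            raise ValueError("min_region_area and closing_radius must be >= 0")


@dataclass
class GapMorphometrics:
    """Shape descriptors of the wound in one frame (μm / hours / degrees)."""

    t: float
    area: float
    centroid_x: float = math.nan
    centroid_y: float = math.nan
    semi_major: float = math.nan
    semi_minor: float = math.nan
    orientation_deg: float = math.nan
    circularity: float = math.nan
    tissue_width: float = math.nan
    closed: bool = False
    flags: str = ""


@dataclass
class MorphometricsSeries:
    """Ordered per-frame gap morphometrics plus the parameters that made them."""

    frames: list[GapMorphometrics]
    params: SegmentationParams | None = None
    pixel_size: float = 1.0
    closure_threshold: float = DEFAULT_CLOSURE_THRESHOLD
    diagnostics: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = self.times
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.t for f in self.frames])

    @property
    def areas(self) -> np.ndarray:
        return np.array([f.area for f in self.frames])

    @property
    def centroids(self) -> np.ndarray:
        return np.array([[f.centroid_x, f.centroid_y] for f in self.frames])

    @property
    def closed(self) -> np.ndarray:
        return np.array([f.closed for f in self.frames])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_h": [f.t for f in self.frames],
                "area_um2": [f.area for f in self.frames],
                "centroid_x_um": [f.centroid_x for f in self.frames],
                "centroid_y_um": [f.centroid_y for f in self.frames],
                "a_um": [f.semi_major for f in self.frames],
                "b_um": [f.semi_minor for f in self.frames],
                "orientation_deg": [f.orientation_deg for f in self.frames],
                "circularity": [f.circularity for f in self.frames],
                "tissue_width_um": [f.tissue_width for f in self.frames],
                "closed": [f.closed for f in self.frames],
                "flags": [f.flags for f in self.frames],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, pixel_size: float = 1.0,
        closure_threshold: float = DEFAULT_CLOSURE_THRESHOLD,
    ) -> "MorphometricsSeries":
        frames = [
            GapMorphometrics(
                t=row["t_h"],
                area=row["area_um2"],
                centroid_x=row.get("centroid_x_um", math.nan),
                centroid_y=row.get("centroid_y_um", math.nan),
                semi_major=row.get("a_um", math.nan),
                semi_minor=row.get("b_um", math.nan),
                orientation_deg=row.get("orientation_deg", math.nan),
                circularity=row.get("circularity", math.nan),
                tissue_width=row.get("tissue_width_um", math.nan),
                closed=bool(row["closed"]) if "closed" in row else row["area_um2"] < closure_threshold,
                flags=str(row.get("flags", "") or ""),
            )
            for _, row in df.iterrows()
        ]
        return cls(frames, pixel_size=pixel_size, closure_threshold=closure_threshold)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "MorphometricsSeries":
        return cls.from_dataframe(pd.read_csv(path), **kwargs)


def segment_frame(image: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Binary tissue mask of one frame.

    Pixels above the threshold, morphologically closed, with connected
    components smaller than ``min_region_area`` px removed.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_frame expects a 2D image")
    if params.threshold_method == "fixed":
        if params.fixed_threshold is None:
            raise ValueError("fixed threshold_method requires fixed_threshold")
        thr = params.fixed_threshold
    else:
        if img.min() == img.max():
            return np.zeros(img.shape, dtype=bool)
        thr = threshold_otsu(img)
    mask = img > thr
    if params.closing_radius > 0:
        mask = closing(mask, disk(params.closing_radius))
    if params.min_region_area > 1:
        # drop tissue components strictly smaller than min_region_area px
        mask = remove_small_objects(mask, max_size=params.min_region_area - 1)
    return mask


def extract_gap_region(mask: np.ndarray, prev_centroid_px=None):
    """Pixel set of the wound inside a tissue mask.

    Background components touching the image border are "around" the tissue;
    the wound is the largest background component fully enclosed by tissue.
    When several enclosed holes of comparable size exist (>= half the largest)
    and a previous-frame centroid (row, col px) is given, the hole whose
    centroid is nearest to it is chosen.

    Returns
    -------
    pixels : (N, 2) int array of (row, col), empty when there is no hole
    diagnostics : dict with areas of all enclosed holes
    """
    mask = np.asarray(mask, dtype=bool)
    lbl = label(~mask, connectivity=1)
    border = np.unique(
        np.concatenate([lbl[0, :], lbl[-1, :], lbl[:, 0], lbl[:, -1]])
    )
    border = set(int(b) for b in border if b != 0)
    holes = [r for r in regionprops(lbl) if r.label not in border]
    diagnostics = {"hole_areas_px": sorted((int(r.area) for r in holes), reverse=True)}
    if not holes:
        return np.empty((0, 2), dtype=int), diagnostics
    max_area = max(r.area for r in holes)
    if prev_centroid_px is not None:
        candidates = [r for r in holes if r.area >= 0.5 * max_area]
        prev = np.asarray(prev_centroid_px, dtype=float)
        chosen = min(candidates, key=lambda r: float(np.hypot(*(np.asarray(r.centroid) - prev))))
    else:
        chosen = max(holes, key=lambda r: r.area)
    diagnostics["n_holes"] = len(holes)
    return np.argwhere(lbl == chosen.label), diagnostics


def _perimeter_um(pixels: np.ndarray, pixel_size: float) -> float:
    """Crofton-formula perimeter of a pixel set, in μm.

    Unlike the raw pixel-edge (or marching-squares) polygon length, the
    Crofton estimator is unbiased for smooth boundaries regardless of their
    orientation, so a rasterized disc measures circularity ~1.
    """
    rmin, cmin = pixels.min(axis=0)
    rmax, cmax = pixels.max(axis=0)
    local = np.zeros((rmax - rmin + 3, cmax - cmin + 3), dtype=bool)
    local[pixels[:, 0] - rmin + 1, pixels[:, 1] - cmin + 1] = True
    return float(perimeter_crofton(local, directions=4)) * pixel_size


def measure_gap(
    gap_pixels: np.ndarray,
    pixel_size: float,
    t: float = 0.0,
    closure_threshold: float = DEFAULT_CLOSURE_THRESHOLD,
) -> GapMorphometrics:
    """Shape descriptors of a gap pixel set.

    Area is pixel count x pixel_size²; the centroid is the mean pixel-center
    position; the equivalent ellipse comes from the second central moments
    (semi-axes 2*sqrt(eigenvalues) of the coordinate covariance, orientation
    the principal-eigenvector angle from the x-axis); circularity is
    4*pi*A/P² with a Crofton-formula perimeter.  An empty set yields area 0
    and ``closed=True``; frames below the closure threshold report their area
    but null ellipse fields.
    """
    pixels = np.asarray(gap_pixels)
    n = pixels.shape[0]
    area = n * pixel_size**2
    closed = area < closure_threshold
    if n == 0:
        return GapMorphometrics(t=t, area=0.0, closed=True)
    x = pixels[:, 1] * pixel_size
    y = pixels[:, 0] * pixel_size
    gm = GapMorphometrics(
        t=t, area=area, centroid_x=float(x.mean()), centroid_y=float(y.mean()), closed=closed
    )
    if closed or n < 5:
        return gm
    dx = x - x.mean()
    dy = y - y.mean()
    mu20 = float(np.mean(dx * dx))
    mu02 = float(np.mean(dy * dy))
    mu11 = float(np.mean(dx * dy))
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    gm.semi_major = 2.0 * math.sqrt(evals[1])
    gm.semi_minor = 2.0 * math.sqrt(evals[0])
    major = evecs[:, 1]
    gm.orientation_deg = math.degrees(math.atan2(major[1], major[0]))
    if gm.orientation_deg <= -90.0:
        gm.orientation_deg += 180.0
    elif gm.orientation_deg > 90.0:
        gm.orientation_deg -= 180.0
    perim = _perimeter_um(pixels, pixel_size)
    if perim and perim > 0:
        gm.circularity = 4.0 * math.pi * area / perim**2
    return gm


def tissue_width(
    mask: np.ndarray,
    pixel_size: float,
    axis_angle_deg: float = 0.0,
    midspan_fraction: float = 0.5,
) -> float:
    """Tissue width in μm: median extent perpendicular to the tissue axis.

    The mask's pixel coordinates are projected onto the inter-cantilever
    axis (``axis_angle_deg`` from the image x-axis) and its perpendicular;
    within each 1-px bin along the axis the perpendicular extent
    (max - min + 1 px) is taken, and the median over the central
    ``midspan_fraction`` of occupied bins is returned.  Holes do not reduce
    the width — it is an extent, not a solid thickness.
    """
    mask = np.asarray(mask, dtype=bool)
    pts = np.argwhere(mask)
    if pts.shape[0] == 0:
        raise ValueError("empty mask")
    phi = math.radians(axis_angle_deg)
    x = pts[:, 1].astype(float)
    y = pts[:, 0].astype(float)
    u = x * math.cos(phi) + y * math.sin(phi)
    v = -x * math.sin(phi) + y * math.cos(phi)
    bins = np.round(u).astype(int)
    umin, umax = bins.min(), bins.max()
    span = umax - umin
    lo = umin + (1 - midspan_fraction) / 2 * span
    hi = umax - (1 - midspan_fraction) / 2 * span
    sel = (bins >= lo) & (bins <= hi)
    bins_sel = bins[sel]
    v_sel = v[sel]
    order = np.argsort(bins_sel, kind="stable")
    bins_sorted = bins_sel[order]
    v_sorted = v_sel[order]
    extents = []
    start = 0
    while start < bins_sorted.size:
        stop = np.searchsorted(bins_sorted, bins_sorted[start], side="right")
        seg = v_sorted[start:stop]
        extents.append(seg.max() - seg.min() + 1.0)
        start = stop
    return float(np.median(extents)) * pixel_size


def morphometrics_series(
    stack: FrameStack,
    params: SegmentationParams | None = None,
    closure_threshold: float = DEFAULT_CLOSURE_THRESHOLD,
    axis_angle_deg: float = 0.0,
) -> MorphometricsSeries:
    """Segment and measure every frame of a tissue stack.

    Per-frame failures are collected in ``diagnostics`` rather than raised.
    Once the gap has closed, later frames count as reopened only when their
    hole exceeds twice the closure threshold (and are then flagged); smaller
    holes are treated as noise and kept closed.
    """
    params = params or SegmentationParams()
    frames: list[GapMorphometrics] = []
    diagnostics: list[dict] = []
    prev_centroid_px = None
    has_closed = False
    for i, (img, t) in enumerate(zip(stack.frames, stack.times)):
        diag: dict = {"frame": i}
        try:
            mask = segment_frame(img, params)
            pixels, gap_diag = extract_gap_region(mask, prev_centroid_px)
            diag.update(gap_diag)
            gm = measure_gap(pixels, stack.pixel_size, t=t, closure_threshold=closure_threshold)
            if mask.any():
                gm.tissue_width = tissue_width(mask, stack.pixel_size, axis_angle_deg)
            if has_closed and not gm.closed:
                if gm.area > 2.0 * closure_threshold:
                    gm.flags = "reopened"
                else:
                    gm = GapMorphometrics(t=t, area=gm.area, tissue_width=gm.tissue_width, closed=True)
            if gm.closed:
                has_closed = True
            elif not math.isnan(gm.centroid_x):
                prev_centroid_px = (
                    gm.centroid_y / stack.pixel_size,
                    gm.centroid_x / stack.pixel_size,
                )
        except Exception as exc:  # per-frame errors are not fatal
            diag["error"] = repr(exc)
            gm = GapMorphometrics(t=t, area=math.nan, closed=False, flags="error")
        frames.append(gm)
        diagnostics.append(diag)
    return MorphometricsSeries(
        frames,
        params=params,
        pixel_size=stack.pixel_size,
        closure_threshold=closure_threshold,
        diagnostics=diagnostics,
    )
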