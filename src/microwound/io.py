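"""Calibrated image-stack I/O and confocal-style preprocessing.

Conventions used throughout the package:

* pixel coordinates are (row, col), 0-based, pixel-center; the physical
  position of pixel ``(i, j)`` is ``(x, y) = (j * pixel_size, i * pixel_size)``
  in micrometres,
* all public tables report micrometres and hours,
* calibration (``pixel_size``, ``frame_interval``) is always supplied by the
  caller / config, never read from TIFF metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy import ndimage as ndi
from skimage.morphology import disk


@dataclass
class FrameStack:
    """A calibrated T x H x W intensity stack for one imaging channel.

    Parameters
    ----------
    frames:
        Array of non-negative finite intensities.  A 2D array is promoted to
        a single-frame stack.
    pixel_size:
        Lateral calibration in micrometres per pixel (> 0).
    frame_interval:
        Time between consecutive frames in hours (> 0).
    channel_name:
        Free-text label (e.g. ``"tissue"``, ``"nuclei"``, ``"beads"``).
    t0:
        Time of the first frame in hours, on an axis where wounding = 0.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_name: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim == 2:
            f = f[None, :, :]
        if f.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {f.shape}")
        if f.shape[0] < 1:
            raise ValueError("zero frames")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0")
        if not (self.frame_interval > 0):
            raise ValueError("frame_interval must be > 0")
        if not np.all(np.isfinite(f)):
            raise ValueError("intensities must be finite")
        if f.min() < 0:
            raise ValueError("intensities must be non-negative")
        self.frames = f

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def times(self) -> np.ndarray:
        """Frame times in hours (wounding at t = 0)."""
        return self.t0 + np.arange(self.n_frames) * self.frame_interval


def load_stack(
    path,
    pixel_size: float,
    frame_interval: float,
    channel_name: str = "",
    t0: float = 0.0,
) -> FrameStack:
    """Load a multi-frame grayscale TIFF as a :class:`FrameStack`.

    Frames are returned in acquisition (page) order.  RGB/multi-sample TIFFs
    are rejected, as are stacks whose pages differ in shape.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(path) as tf:
        pages = tf.pages
        if len(pages) == 0:
            raise ValueError("zero frames")
        shapes = set()
        for page in pages:
            if getattr(page, "samplesperpixel", 1) > 1:
                raise ValueError("non-grayscale input")
            shapes.add(page.shape)
        if len(shapes) > 1:
            raise ValueError(f"frames differ in shape: {sorted(shapes)}")
        arr = tf.asarray()
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("non-grayscale input")
    return FrameStack(arr, pixel_size, frame_interval, channel_name=channel_name, t0=t0)


def save_stack(stack: FrameStack, path) -> Path:
    """Write a :class:`FrameStack` to a multi-page grayscale TIFF.

    The intensity round-trip through :func:`load_stack` is bit-exact.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    return path


def preprocess_confocal(zstack, median_radius: int = 1, rescale: bool = True) -> np.ndarray:
    """Collapse a confocal z-stack to a single denoised 2D image.

    Each slice is median-filtered (disk footprint of ``median_radius`` pixels;
    0 disables filtering), log-transformed as ``log(1 + x)`` to compress the
    histogram while handling zeros, then the maximum projection over z is
    taken.  With ``rescale=True`` (default) the projection is linearly mapped
    to [0, 1]; a constant positive projection maps to 1.0, a constant zero
    projection to 0.0.

    Before rescaling the operation is pointwise monotone in its input.
    """
    z = np.asarray(zstack, dtype=float)
    if z.ndim == 2:
        z = z[None]
    if z.ndim != 3 or z.shape[0] < 1 or z.size == 0:
        raise ValueError("empty stack")
    if not np.all(np.isfinite(z)) or z.min() < 0:
        raise ValueError("intensities must be finite and non-negative")
    if median_radius < 0:
        raise ValueError("median_radius must be >= 0")
    footprint = disk(median_radius) if median_radius > 0 else None
    slices = []
    for s in z:
        if footprint is not None:
            s = ndi.median_filter(s, footprint=footprint, mode="reflect")
        slices.append(np.log1p(s))
    proj = np.max(slices, axis=0)
    if not rescale:
        return proj
    lo, hi = float(proj.min()), float(proj.max())
    if hi == lo:
        return (proj > 0).astype(float)
    return (proj - lo) / (hi - lo)


def read_config(path) -> dict:
    """Read a YAML (or JSON, a YAML subset) run-configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def write_config(cfg: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return path
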