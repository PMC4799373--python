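import numpy as np
import pytest
from hypothesis import settings

import microwound as mw

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cfg() -> mw.SceneConfig:
    """Default study conditions: 512 px field, 30-min frames for 24 h,
    30,000 μm² gap closing at 1,344 μm² h⁻¹, 200 cells, moderate noise."""
    return mw.SceneConfig(seed=2)


@pytest.fixture(scope="session")
def default_scene(default_cfg) -> mw.SyntheticScene:
    return mw.render_scene(default_cfg)


@pytest.fixture(scope="session")
def default_series(default_scene) -> mw.MorphometricsSeries:
    return mw.morphometrics_series(default_scene.tissue)


@pytest.fixture(scope="session")
def default_spots(default_cfg, default_scene):
    """Per-frame nuclei detections on the default scene."""
    return mw.detect_nuclei_stack(
        default_scene.nuclei, blob_sigma=default_cfg.nucleus_sigma, detect_threshold=0.2
    )


def small_scene_config(**overrides) -> mw.SceneConfig:
    """A fast-rendering scene: 256 px field, 8,000 μm² gap, no cells/noise
    unless overridden.  The gap closes within the movie (~7.7 h)."""
    kw = dict(
        image_shape=(256, 256),
        band_width=320.0,
        initial_gap_area=8_000.0,
        closure_rate=1_200.0,
        n_cells=0,
        noise_sd=0.0,
        seed=0,
    )
    kw.update(overrides)
    return mw.SceneConfig(**kw)


@pytest.fixture(scope="session")
def small_noiseless_scene():
    cfg = small_scene_config()
    return cfg, mw.render_scene(cfg)


def rasterize_ellipse(a_px: float, b_px: float, angle_deg: float = 0.0, pad: int = 8):
    """Binary pixel-center rasterization of an ellipse (independent of the
    renderer's coverage model)."""
    phi = np.deg2rad(angle_deg)
    n = int(np.ceil(max(a_px, b_px))) + pad
    cy = cx = n
    yy, xx = np.mgrid[0 : 2 * n + 1, 0 : 2 * n + 1]
    u = (xx - cx) * np.cos(phi) + (yy - cy) * np.sin(phi)
    v = -(xx - cx) * np.sin(phi) + (yy - cy) * np.cos(phi)
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


def moment_oracle(pixels: np.ndarray, pixel_size: float = 1.0):
    """Exhaustive-summation moment oracle: centroid, semi-axes and
    orientation computed with explicit loops over the pixel list."""
    n = len(pixels)
    sx = sy = 0.0
    for r, c in pixels:
        sx += c * pixel_size
        sy += r * pixel_size
    mx, my = sx / n, sy / n
    sxx = syy = sxy = 0.0
    for r, c in pixels:
        dx = c * pixel_size - mx
        dy = r * pixel_size - my
        sxx += dx * dx
        syy += dy * dy
        sxy += dx * dy
    mu20, mu02, mu11 = sxx / n, syy / n, sxy / n
    common = np.sqrt((mu20 - mu02) ** 2 + 4 * mu11**2)
    l1 = (mu20 + mu02 + common) / 2
    l2 = (mu20 + mu02 - common) / 2
    theta = 0.5 * np.arctan2(2 * mu11, mu20 - mu02)
    return {
        "area": n * pixel_size**2,
        "centroid": (mx, my),
        "a": 2 * np.sqrt(l1),
        "b": 2 * np.sqrt(max(l2, 0.0)),
        "orientation_deg": np.rad2deg(theta),
    }


def link_identity_accuracy(trackset, spots, gt_tracks, match_radius=5.0):
    """Fraction of tracker links whose endpoints match the same ground-truth
    cell (nearest ground-truth position within match_radius μm)."""
    from scipy.spatial import cKDTree

    ids_per_frame = []
    for f in range(gt_tracks.shape[1]):
        tree = cKDTree(gt_tracks[:, f])
        d, idx = tree.query(np.asarray(spots[f]).reshape(-1, 2))
        ids_per_frame.append(np.where(d < match_radius, idx, -1))
    correct = total = 0
    for tr in trackset.tracks:
        for a in range(len(tr.frames) - 1):
            f0, f1 = int(tr.frames[a]), int(tr.frames[a + 1])
            s0 = np.asarray(spots[f0]).reshape(-1, 2)
            s1 = np.asarray(spots[f1]).reshape(-1, 2)
            i0 = int(np.argmin(np.hypot(*(s0 - tr.xy[a]).T)))
            i1 = int(np.argmin(np.hypot(*(s1 - tr.xy[a + 1]).T)))
            g0, g1 = ids_per_frame[f0][i0], ids_per_frame[f1][i1]
            total += 1
            correct += int(g0 >= 0 and g0 == g1)
    return correct / total if total else float("nan")
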