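"""Plot helpers: gap-area kinetics, windrose, tension time course."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .kinetics import ClosureKinetics
from .morphometrics import MorphometricsSeries
from .tension import TensionSeries

__all__ = ["plot_gap_area", "plot_windrose", "plot_tension"]


def plot_gap_area(series: MorphometricsSeries, kin: ClosureKinetics | None = None, ax=None):
    """Gap area vs time, optionally with the fitted closing line."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(series.times, series.areas, "o-", ms=3, label="gap area")
    if kin is not None:
        t0, t1 = kin.fit_window
        tt = np.linspace(t0, t1, 50)
        a0 = kin.peak_area
        ax.plot(tt, a0 - kin.closure_rate * (tt - kin.peak_time), "--",
                label=f"fit: {kin.closure_rate:.0f} μm²/h")
        ax.legend()
    ax.set_xlabel("time after wounding (h)")
    ax.set_ylabel("gap area (μm²)")
    return ax


def plot_windrose(hist, ax=None):
    """Half-polar windrose from a windrose() dataframe (0° toward the gap)."""
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    centers = np.deg2rad((hist["bin_start_deg"] + hist["bin_end_deg"]) / 2.0)
    widths = np.deg2rad(hist["bin_end_deg"] - hist["bin_start_deg"])
    ax.bar(centers, hist["percent"], width=widths, bottom=0.0, alpha=0.7, edgecolor="k")
    ax.set_thetamin(0)
    ax.set_thetamax(180)
    ax.set_xlabel("radial migration angle (°); frequency (%)")
    return ax


def plot_tension(series: TensionSeries, normalized: bool = False, ax=None):
    """Tension vs time with the pre-wound baseline as a dashed line."""
    if ax is None:
        _, ax = plt.subplots()
    y = series.normalized() if normalized else series.tension
    base = 1.0 if normalized else series.baseline_tension
    ax.plot(series.times, y, "o-", ms=3)
    ax.axhline(base, ls="--", color="gray", label="baseline")
    ax.set_xlabel("time after wounding (h)")
    ax.set_ylabel("tension (baseline units)" if normalized else "tension (μN)")
    ax.legend()
    return ax
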