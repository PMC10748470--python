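"""Publication-style figures: actograms, periodograms, polar profiles."""

from __future__ import annotations

import numpy as np

from .circadian_analysis import Periodogram
from .rhythm_series import Actogram


def plot_actogram(actogram: Actogram, ax=None, cmap: str = "Greys"):
    """Double-plotted actogram raster (rows = days, x = 48 h)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    m = actogram.matrix
    ax.imshow(
        np.nan_to_num(m, nan=0.0),
        aspect="auto",
        cmap=cmap,
        interpolation="nearest",
        extent=(0, 48, m.shape[0], 0),
        vmin=0,
        vmax=1,
    )
    ax.set_xlabel("time (h)")
    ax.set_ylabel("day")
    ax.set_xticks([0, 12, 24, 36, 48])
    return ax


def plot_periodogram(pg: Periodogram, ax=None):
    """LS power vs period with the alpha-level significance cutoff."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(pg.period_h, pg.power, lw=1)
    ax.axhline(pg.threshold, color="red", ls="--", lw=1, label=f"alpha={pg.alpha:g}")
    if pg.is_rhythmic:
        ax.axvline(pg.best_period, color="0.6", lw=0.8)
    ax.set_xlabel("period (h)")
    ax.set_ylabel("LS power")
    ax.legend(frameon=False)
    return ax


def plot_polar(edges_zt: np.ndarray, profile: np.ndarray, ax=None):
    """Wrapped 24-h polar profile; radius is mean singing value in [0, 1]."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
    theta = edges_zt * 2 * np.pi / 24.0
    r = np.nan_to_num(profile, nan=0.0)
    theta = np.append(theta, theta[0])
    r = np.append(r, r[0])
    ax.plot(theta, r, lw=1.2)
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.set_xticks(np.arange(0, 2 * np.pi, np.pi / 2))
    ax.set_xticklabels(["ZT0", "ZT6", "ZT12", "ZT18"])
    ax.set_ylim(0, 1)
    return ax
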