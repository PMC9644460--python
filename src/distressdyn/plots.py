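"""Basic band plots for fitted trajectories (matplotlib)."""

from __future__ import annotations

import numpy as np

from .dynamics import TIME_ORIGIN

__all__ = ["plot_bands"]


def plot_bands(band_df, ax=None, observed=None, label=None, color="0.3"):
    """Plot a pointwise credible band table from ``trajectory_bands``.

    ``band_df`` has columns time, q2.5, q25, q50, q75, q97.5; the x axis is
    calendar years. ``observed`` is an optional (year, value) DataFrame
    overlaid as open circles.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    years = TIME_ORIGIN + np.asarray(band_df["time"], float)
    ax.fill_between(years, band_df["q2.5"], band_df["q97.5"],
                    color=color, alpha=0.2, linewidth=0)
    ax.fill_between(years, band_df["q25"], band_df["q75"],
                    color=color, alpha=0.4, linewidth=0)
    ax.plot(years, band_df["q50"], color=color, label=label)
    if observed is not None:
        ax.plot(observed["year"] + 0.5, observed["value"], "o",
                mfc="none", color="tab:red")
    ax.set_xlabel("year")
    if label:
        ax.legend()
    return ax
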