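"""Plotting helpers: abundance surfaces, core-range masks, rho-sigma paths.

Each function draws onto a provided axes (or creates one) and returns the
axes, so figures compose in scripts and notebooks.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_surface", "plot_core_range", "plot_trajectory"]


def plot_surface(x, y, surface, ax=None, title=None, cbar_label="log(predicted count)"):
    """Heat map of a predicted log-abundance surface on a regular grid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.pcolormesh(x, y, surface, shading="auto", cmap="viridis")
    ax.figure.colorbar(im, ax=ax, label=cbar_label)
    ax.set_xlabel("lon")
    ax.set_ylabel("lat")
    if title:
        ax.set_title(title)
    return ax


def plot_core_range(x, y, mask, ax=None, title=None, color="crimson"):
    """Binary core-range mask (cells at/above the abundance quantile)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    shown = np.where(mask.mask if hasattr(mask, "mask") else mask, 1.0, np.nan)
    ax.pcolormesh(x, y, shown, shading="auto", cmap="Reds", vmin=0, vmax=1.2)
    ax.set_xlabel("lon")
    ax.set_ylabel("lat")
    if title:
        ax.set_title(title)
    return ax


def plot_trajectory(trajectory, ax=None, annotate=True):
    """rho-sigma path of annual fits: sigma on x, rho on y (inverted).

    Large rho (flat, structureless field) plots at the bottom; movement
    toward the lower left is the erosion signature.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ok = trajectory.valid()
    ax.plot(ok["sigma"], ok["rho"], "-o", color="steelblue", ms=4)
    if annotate:
        for _, r in ok.iterrows():
            ax.annotate(str(int(r["year"])), (r["sigma"], r["rho"]), fontsize=7)
    ax.set_yscale("log")
    ax.set_xscale("log")
    ax.invert_yaxis()
    ax.set_xlabel("spatial variance sigma_t")
    ax.set_ylabel("connectivity rho_t (large = structureless)")
    return ax
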