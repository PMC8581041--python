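"""Quick-look figures: landscape heatmaps, flux quivers, path overlays."""

from __future__ import annotations

from typing import Optional

import numpy as np
import matplotlib.pyplot as plt

from .landscape import LandscapeGrid, AttractorSet
from .flux import FluxField
from .transitions import TransitionPathSet


def plot_landscape(grid: LandscapeGrid, ax=None, cmap: str = "viridis_r",
                   attractors: Optional[AttractorSet] = None):
    """Heatmap of U(r1, r2); unvisited bins are blank.

    Low potential (high occupancy) plots dark with the default reversed
    colormap, echoing the usual basin rendering.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.2))
    U = np.ma.masked_invalid(grid.U)
    mesh = ax.pcolormesh(grid.edges1, grid.edges2, U.T, cmap=cmap,
                         shading="flat")
    plt.colorbar(mesh, ax=ax, label="U = -ln P_ss")
    if attractors is not None:
        for m in attractors:
            ax.plot(*m.position, "w*", markersize=10, markeredgecolor="k")
            if m.label:
                ax.annotate(m.label, m.position, textcoords="offset points",
                            xytext=(6, 6), color="w", fontsize=9)
    ax.set_xlabel("r1 (spikes/s)")
    ax.set_ylabel("r2 (spikes/s)")
    return ax


def plot_flux(flux: FluxField, ax=None, min_magnitude: float = 0.0,
              color: str = "w"):
    """Quiver of the per-box flux vectors over the current axes."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.2))
    c1, c2 = np.meshgrid(flux.grid.centers1, flux.grid.centers2,
                         indexing="ij")
    mask = flux.magnitude >= min_magnitude
    ax.quiver(c1[mask], c2[mask], flux.Jx[mask], flux.Jy[mask],
              color=color, width=0.004)
    ax.set_xlabel("r1 (spikes/s)")
    ax.set_ylabel("r2 (spikes/s)")
    return ax


def plot_mean_path(path_set: TransitionPathSet, ax=None, color: str = "m"):
    """Overlay an averaged transition path (after ``average_path``)."""
    if path_set.mean_path is None:
        raise ValueError("average the path set first")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.2))
    ax.plot(path_set.mean_path[:, 0], path_set.mean_path[:, 1], color=color,
            lw=2, label=f"{path_set.from_label} -> {path_set.to_label} "
                        f"(K={path_set.K})")
    ax.legend(loc="best", fontsize=8)
    return ax
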