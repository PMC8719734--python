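"""Plotting helpers: lattice maps, trajectories and polar phase histograms."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_map", "plot_trajectories", "polar_phase_histogram"]


def plot_map(values: np.ndarray, ax=None, title: str | None = None,
             cmap: str = "viridis", **imshow_kwargs):
    """Heat map of a per-location quantity on its lattice layout."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(np.asarray(values), cmap=cmap, origin="upper",
                   **imshow_kwargs)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    return ax


def plot_trajectories(ensemble, ax=None, max_paths: int = 20, alpha=0.4):
    """Molecular paths over time (history segment shaded)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    k = min(max_paths, ensemble.paths.shape[0])
    for i in range(k):
        ax.plot(ensemble.times, ensemble.paths[i], lw=0.8, alpha=alpha)
    ax.axvspan(ensemble.times[0], 0.0, color="0.9", zorder=0)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("mRNA copies")
    return ax


def polar_phase_histogram(phases: np.ndarray, ax=None, bins: int = 36,
                          title: str | None = None):
    """Polar histogram of wrapped phase shifts (radians)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    phases = np.asarray(phases).ravel()
    counts, edges = np.histogram(phases, bins=bins, range=(-np.pi, np.pi))
    widths = np.diff(edges)
    ax.bar(edges[:-1] + widths / 2, counts, width=widths, bottom=0.0,
           alpha=0.8, edgecolor="k", linewidth=0.3)
    if title:
        ax.set_title(title)
    return ax
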