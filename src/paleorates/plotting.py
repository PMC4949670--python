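"""Optional matplotlib figures: rates through time and boundary comparisons."""
from __future__ import annotations

import numpy as np

from .likelihoods import EpochGrid
from .posterior import BoundaryComparison, RateSummary

_COLORS = {"lambda": "#1f77b4", "mu": "#2ca02c", "net": "0.45"}
_NAMES = {"lambda": "origination", "mu": "extinction", "net": "net diversification"}


def plot_rates_through_time(summary: RateSummary, grid: EpochGrid, ax=None,
                            kinds=("lambda", "mu")):
    """Step plot of posterior mean rates with shaded 95% HPD bands."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    b = grid.boundaries.copy()
    if not np.isfinite(b[0]):
        b[0] = summary.table["older_bound"].replace(np.inf, np.nan).max()
        if not np.isfinite(b[0]):
            b[0] = b[1] * 1.1
    edges = np.repeat(b, 2)[1:-1]
    for kind in kinds:
        mean = np.repeat(summary.table[f"{kind}_mean"].to_numpy(), 2)
        lo = np.repeat(summary.table[f"{kind}_hpd_lo"].to_numpy(), 2)
        hi = np.repeat(summary.table[f"{kind}_hpd_hi"].to_numpy(), 2)
        ax.plot(edges, mean, color=_COLORS[kind], label=_NAMES[kind])
        ax.fill_between(edges, lo, hi, color=_COLORS[kind], alpha=0.25, lw=0)
    ax.set_xlabel("time (Ma)")
    ax.set_ylabel("rate (events lineage$^{-1}$ Myr$^{-1}$)")
    ax.invert_xaxis()
    ax.legend(frameon=False)
    return ax


def plot_boundary_comparison(comp: BoundaryComparison, ax=None):
    """Paired posterior densities before and after one boundary."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    for samples, label, color in ((comp.before, "before", "0.3"),
                                  (comp.after, "after", _COLORS["lambda"])):
        counts, edges = np.histogram(samples, bins=60, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        ax.plot(centers, counts / counts.max(), label=label, color=color)
    arrow = {"increase": "↑", "decrease": "↓", "none": ""}[comp.direction]
    flag = f" {arrow}" if comp.significant else ""
    ax.set_title(f"{comp.boundary_name} {comp.kind}{flag}", fontsize=10)
    ax.set_xlabel("rate (events lineage$^{-1}$ Myr$^{-1}$)")
    ax.set_ylabel("relative density")
    ax.legend(frameon=False, fontsize=8)
    return ax
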