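"""Posterior summaries: pooled replicate chains, HPD intervals,
rates-through-time tables, rate-shift tests at epoch boundaries, and
clade-origin age samples."""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .likelihoods import EpochGrid
from .sampler import Trace

logger = logging.getLogger(__name__)

__all__ = [
    "PooledSamples",
    "RateSummary",
    "BoundaryComparison",
    "combine_replicates",
    "hpd",
    "rates_through_time",
    "shift_significant",
    "boundary_comparison",
    "clade_origin_samples",
]


@dataclass
class PooledSamples:
    """Burned-in posterior samples pooled across replicate chains."""

    data: pd.DataFrame
    labels: tuple[str, ...]
    taxa: tuple[str, ...] = ()
    groups: tuple[str, ...] = ()
    ts: np.ndarray | None = None
    te: np.ndarray | None = None

    def rate_samples(self, bin_index: int, kind: str) -> np.ndarray:
        """Posterior samples of one per-epoch rate (0-based bin, oldest first)."""
        prefix = {"origination": "lambda_", "extinction": "mu_"}[kind]
        return self.data[f"{prefix}{bin_index + 1}"].to_numpy()


def combine_replicates(traces: list[Trace], burnin_frac: float = 0.2
                       ) -> PooledSamples:
    """Drop the first ``ceil(burnin_frac * n)`` samples of each chain and pool.

    All traces must share the same parameter layout (epoch grid and, when
    per-taxon times are stored, the same taxa).
    """
    if not traces:
        raise ValueError("need at least one trace")
    ref = traces[0]
    for t in traces[1:]:
        if tuple(t.data.columns) != tuple(ref.data.columns) or t.labels != ref.labels:
            raise ValueError("traces have mismatched parameter layouts")
        if t.taxa != ref.taxa:
            raise ValueError("traces cover different taxa")
    frames, ts_parts, te_parts = [], [], []
    for t in traces:
        skip = math.ceil(burnin_frac * t.n_samples)
        frames.append(t.data.iloc[skip:])
        if t.ts is not None:
            ts_parts.append(t.ts[skip:])
            te_parts.append(t.te[skip:])
    data = pd.concat(frames, ignore_index=True)
    ts = np.concatenate(ts_parts) if ts_parts else None
    te = np.concatenate(te_parts) if te_parts else None
    return PooledSamples(data=data, labels=ref.labels, taxa=ref.taxa,
                         groups=ref.groups, ts=ts, te=te)


def hpd(samples, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval of the sorted samples holding ``prob`` mass.

    The interval contains ``ceil(prob * n)`` samples; ties between equally
    short windows are broken by the lowest start index.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least two samples")
    m = int(math.ceil(prob * n))
    m = min(max(m, 1), n)
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


@dataclass
class RateSummary:
    """Per-epoch posterior means and 95% HPD bounds of lambda, mu and net rate."""

    table: pd.DataFrame

    def __post_init__(self):
        for kind in ("lambda", "mu", "net"):
            mean = self.table[f"{kind}_mean"]
            slack = 1e-9 * (1.0 + mean.abs())   # mean of a constant chain can
            bad = ((mean < self.table[f"{kind}_hpd_lo"] - slack)   # round off
                   | (mean > self.table[f"{kind}_hpd_hi"] + slack))
            if bad.any():
                raise ValueError(f"HPD bounds fail to bracket the mean for {kind}")


def rates_through_time(pooled: PooledSamples, grid: EpochGrid,
                       prob: float = 0.95) -> RateSummary:
    """Posterior mean and HPD of origination, extinction and net rate per bin.

    Net diversification is computed sample-wise as ``lambda - mu`` (keeping
    the posterior correlation of the two rates) and then summarized.
    """
    rows = []
    for j in range(grid.n_bins):
        lam = pooled.rate_samples(j, "origination")
        mu = pooled.rate_samples(j, "extinction")
        net = lam - mu
        row = {"label": grid.labels[j],
               "older_bound": grid.boundaries[j],
               "younger_bound": grid.boundaries[j + 1]}
        for kind, x in (("lambda", lam), ("mu", mu), ("net", net)):
            lo_b, hi_b = hpd(x, prob)
            row[f"{kind}_mean"] = float(x.mean())
            row[f"{kind}_hpd_lo"] = lo_b
            row[f"{kind}_hpd_hi"] = hi_b
        rows.append(row)
    return RateSummary(pd.DataFrame(rows))


def shift_significant(samples_a, samples_b, prob: float = 0.95) -> bool:
    """Two-sided HPD rule for a significant rate difference.

    True iff the mean of each sample set lies outside the ``prob`` HPD of
    the other — both conditions are required.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    lo_b, hi_b = hpd(b, prob)
    lo_a, hi_a = hpd(a, prob)
    mean_a, mean_b = a.mean(), b.mean()
    return bool((mean_a < lo_b or mean_a > hi_b)
                and (mean_b < lo_a or mean_b > hi_a))


@dataclass
class BoundaryComparison:
    """Posterior rate change across one geological boundary."""

    boundary_name: str
    boundary_age: float
    group: str
    kind: str                       # "origination" | "extinction"
    before: np.ndarray              # samples of the older flanking bin
    after: np.ndarray               # samples of the younger flanking bin
    significant: bool
    fold_change: float
    direction: str                  # "increase" | "decrease" | "none"
    exact_edge: bool                # False when the nearest grid edge was used

    def __post_init__(self):
        if self.significant != shift_significant(self.before, self.after):
            raise ValueError("significance flag inconsistent with stored samples")


def boundary_comparison(pooled: PooledSamples, grid: EpochGrid,
                        boundary_age: float, kind: str = "origination",
                        group: str = "", boundary_name: str = "",
                        tol: float = 1e-6) -> BoundaryComparison:
    """Compare posterior rates in the bins flanking a geological boundary.

    ``before`` is the bin just older than the boundary, ``after`` the bin
    just younger.  When the requested age is not a grid edge (a stage
    boundary internal to an epoch), the nearest interior edge is used and
    the result flagged.  The fold change is the ratio of posterior means,
    oriented along the direction of change.
    """
    b = grid.boundaries
    if not (b[-1] < boundary_age < b[0]):
        raise ValueError("boundary_age must lie strictly inside the grid")
    interior = b[1:-1]
    if interior.size == 0:
        raise ValueError("grid has a single bin; no boundary to compare across")
    dist = np.abs(interior - boundary_age)
    m = int(np.argmin(dist)) + 1          # index into the boundaries vector
    exact = bool(dist[m - 1] <= tol)
    if not exact:
        logger.warning("age %.3f Ma is not a grid edge; using the nearest edge "
                       "%.3f Ma (%s | %s)", boundary_age, b[m],
                       grid.labels[m - 1], grid.labels[m])
    before = pooled.rate_samples(m - 1, kind)
    after = pooled.rate_samples(m, kind)
    mean_before, mean_after = float(before.mean()), float(after.mean())
    if mean_after == mean_before:
        direction, fold = "none", 1.0
    elif mean_after > mean_before:
        direction, fold = "increase", mean_after / mean_before
    else:
        direction, fold = "decrease", mean_before / mean_after
    return BoundaryComparison(
        boundary_name=boundary_name or f"{b[m]:.1f} Ma",
        boundary_age=float(b[m]), group=group, kind=kind,
        before=before, after=after,
        significant=shift_significant(before, after),
        fold_change=float(fold), direction=direction, exact_edge=exact)


def clade_origin_samples(pooled: PooledSamples,
                         member_taxa: list[str] | None = None) -> np.ndarray:
    """Clade-origin age per posterior sample: the max ``ts`` over member taxa."""
    if pooled.ts is None:
        raise ValueError("pooled samples carry no per-taxon origination times")
    if member_taxa is None:
        cols = np.arange(len(pooled.taxa))
    else:
        index = {name: i for i, name in enumerate(pooled.taxa)}
        missing = [t for t in member_taxa if t not in index]
        if missing:
            raise KeyError(f"taxa not in trace: {missing[:10]}")
        cols = np.array([index[t] for t in member_taxa])
    if cols.size == 0:
        raise ValueError("clade has no member taxa")
    return pooled.ts[:, cols].max(axis=1)


def group_members(pooled: PooledSamples, group: str) -> list[str]:
    """Taxa of a pooled trace belonging to one vegetation group."""
    return [t for t, g in zip(pooled.taxa, pooled.groups) if g == group]
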