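"""Closed-form model components for the joint preservation / birth-death model.

The model treats each fossil genus as a lineage with latent origination time
``ts`` and extinction time ``te`` (both in Ma, present = 0, increasing into
the past).  Fossil occurrences of a taxon are a homogeneous Poisson process
(HPP) with rate ``q`` (occurrences per taxon per Myr) on its lifespan
``[te, ts]``, with gamma-distributed rate heterogeneity across taxa
(mean-one multipliers, shape ``alpha``), discretized into ``K``
equal-probability categories.  Origination and extinction rates ``lambda_j``
and ``mu_j`` are piecewise constant on a fixed grid of geological epochs and
act as the prior over the latent lifespans through a birth-death process.
Rate parameters receive half-Cauchy priors whose scales are themselves
estimated (hyper-priors).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "EpochGrid",
    "ModelState",
    "PriorConfig",
    "gamma_category_rates",
    "preservation_loglik",
    "bd_sufficient_stats",
    "bd_loglik_from_stats",
    "bd_loglik_piecewise",
    "half_cauchy_logpdf",
    "log_prior",
    "log1mexp",
]

_LOG_2_OVER_PI = math.log(2.0 / math.pi)


def log1mexp(x: np.ndarray | float) -> np.ndarray | float:
    """Stable ``log(1 - exp(-x))`` for ``x > 0``.

    Uses ``log(-expm1(-x))`` for small x and ``log1p(-exp(-x))`` for large x
    (switch at log 2), following the standard recipe.
    """
    x_arr = np.asarray(x, dtype=float)
    out = np.empty_like(x_arr)
    small = x_arr <= math.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out[small] = np.log(-np.expm1(-x_arr[small]))
        out[~small] = np.log1p(-np.exp(-x_arr[~small]))
    if np.ndim(x) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class EpochGrid:
    """Ordered geological time bins on which rates are piecewise constant.

    ``boundaries`` is a strictly decreasing vector of ages in Ma,
    ``b_0 > b_1 > ... > b_K = 0``; bin ``j`` (0-based, oldest first) covers
    the half-open interval ``(b_{j+1}, b_j]`` so that an event falling
    exactly on a boundary belongs to the younger bin.  ``b_0`` may be
    ``inf`` for an unbounded oldest bin.
    """

    boundaries: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("need at least two boundaries (one bin)")
        if b[-1] != 0.0:
            raise ValueError("youngest boundary must be exactly 0 Ma")
        if not np.all(np.diff(b) < 0):
            raise ValueError("boundaries must be strictly decreasing")
        object.__setattr__(self, "boundaries", b)
        labels = tuple(self.labels) if self.labels else tuple(
            f"bin_{i + 1}" for i in range(b.size - 1)
        )
        if len(labels) != b.size - 1:
            raise ValueError("need one label per bin")
        object.__setattr__(self, "labels", labels)

    @property
    def n_bins(self) -> int:
        return self.boundaries.size - 1

    def bin_index(self, ages: np.ndarray | float) -> np.ndarray:
        """0-based bin index (oldest bin = 0) for each age.

        Ages exactly at a boundary fall in the younger bin; age 0 is
        assigned to the youngest bin.
        """
        ages_arr = np.atleast_1d(np.asarray(ages, dtype=float))
        asc = self.boundaries[::-1]
        idx = np.searchsorted(asc, ages_arr, side="left")
        j = self.n_bins - idx
        return np.clip(j, 0, self.n_bins - 1)

    def lineage_time(self, ts: np.ndarray, te: np.ndarray) -> np.ndarray:
        """Total lineage-time per bin: sum of overlaps of [te_i, ts_i]."""
        older = self.boundaries[:-1]
        younger = self.boundaries[1:]
        ts_arr = np.asarray(ts, dtype=float)[:, None]
        te_arr = np.asarray(te, dtype=float)[:, None]
        overlap = np.minimum(ts_arr, older[None, :]) - np.maximum(te_arr, younger[None, :])
        return np.clip(overlap, 0.0, None).sum(axis=0)

    def subgrid(self, oldest: float) -> "EpochGrid":
        """Drop bins entirely older than ``oldest`` (keeps the bin containing it)."""
        keep = self.boundaries[1:] < oldest
        first = int(np.argmax(keep))
        return EpochGrid(self.boundaries[first:], self.labels[first:])

    @classmethod
    def from_csv(cls, path) -> "EpochGrid":
        """Read a grid from a CSV with columns label, older_bound_Ma, younger_bound_Ma.

        Rows must be contiguous and ordered old to young.
        """
        df = pd.read_csv(path)
        older = df["older_bound_Ma"].to_numpy(dtype=float)
        younger = df["younger_bound_Ma"].to_numpy(dtype=float)
        if not np.allclose(older[1:], younger[:-1]):
            raise ValueError("epoch rows must be contiguous (older bound of each row "
                             "equal to younger bound of the previous)")
        boundaries = np.concatenate([older[:1], younger])
        return cls(boundaries, tuple(df["label"].astype(str)))

    @classmethod
    def stratigraphic(cls) -> "EpochGrid":
        """The packaged epoch grid of the international stratigraphic timescale."""
        ref = resources.files("paleorates.data") / "epochs.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


@dataclass
class ModelState:
    """Full parameter state of the joint model.

    ``ts``/``te`` are per-taxon origination and extinction times (Ma);
    ``q`` the preservation rate; ``alpha`` the gamma shape of the
    across-taxon preservation heterogeneity; ``lam``/``mu`` per-epoch
    origination and extinction rates; ``sig_l``/``sig_m`` the half-Cauchy
    scale hyper-parameters of the rate priors.
    """

    ts: np.ndarray
    te: np.ndarray
    q: float
    alpha: float
    lam: np.ndarray
    mu: np.ndarray
    sig_l: float = 1.0
    sig_m: float = 1.0

    def copy(self) -> "ModelState":
        return ModelState(self.ts.copy(), self.te.copy(), self.q, self.alpha,
                          self.lam.copy(), self.mu.copy(), self.sig_l, self.sig_m)


def gamma_category_rates(alpha: float, K: int = 8) -> np.ndarray:
    """Mean preservation-rate multipliers of ``K`` equal-probability categories.

    The across-taxon heterogeneity is a mean-one gamma (shape ``alpha``,
    rate ``alpha``).  Each category holds probability mass 1/K and is
    represented by the conditional mean of the distribution inside its
    quantile bin, so the multipliers are increasing and average exactly 1.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        return np.ones(1)
    p = np.linspace(0.0, 1.0, K + 1)
    edges = stats.gamma.ppf(p, a=alpha, scale=1.0 / alpha)
    # E[X; l < X <= u] for X ~ Gamma(a, rate b) is (a/b) * (F_{a+1}(u) - F_{a+1}(l));
    # here a = b = alpha so the prefactor is 1, and each bin mass is 1/K.
    mass = stats.gamma.cdf(edges, a=alpha + 1.0, scale=1.0 / alpha)
    r = K * np.diff(mass)
    return r / r.mean()


def preservation_loglik(n, ts, te, q: float, alpha: float | None = None,
                        K: int = 1, conditional: bool = True,
                        rates: np.ndarray | None = None):
    """Log-likelihood of the fossil occurrences of one or more taxa.

    For a taxon with ``n`` occurrences over lifespan ``d = ts - te``, each
    heterogeneity category ``c`` with rate ``q_c = q * r_c`` contributes the
    HPP log-likelihood ``n*log(q_c) - q_c*d``, conditioned on the taxon
    being sampled at least once (division by ``1 - exp(-q_c*d)``) when
    ``conditional`` is true.  The returned value is the log of the
    equal-weight average over the ``K`` category likelihoods, computed in
    log space.

    Scalars give a scalar; arrays give a per-taxon vector.
    """
    scalar = np.ndim(n) == 0 and np.ndim(ts) == 0 and np.ndim(te) == 0
    n_arr = np.atleast_1d(np.asarray(n, dtype=float))
    ts_arr = np.atleast_1d(np.asarray(ts, dtype=float))
    te_arr = np.atleast_1d(np.asarray(te, dtype=float))
    if np.any(n_arr < 1):
        raise ValueError("every taxon in the data must have >= 1 occurrence")
    if q <= 0:
        raise ValueError("q must be > 0")
    d = ts_arr - te_arr
    if np.any(d <= 0):
        raise ValueError("ts must exceed te for every taxon")
    if rates is None:
        rates = gamma_category_rates(alpha, K) if K > 1 else np.ones(1)
    qr = q * rates
    x = d[:, None] * qr[None, :]
    ll = n_arr[:, None] * np.log(qr)[None, :] - x
    if conditional:
        ll -= log1mexp(x)
    out = logsumexp(ll, axis=1) - math.log(len(rates))
    return float(out[0]) if scalar else out


def bd_sufficient_stats(ts, te, extant, grid: EpochGrid,
                        count_root: bool = False):
    """Per-bin event counts and lineage-time for the birth-death likelihood.

    Returns ``(B, D, S)``: origination events, extinction events, and total
    lineage-time per bin.  The single oldest ``ts`` is the start of the
    process and is excluded from ``B`` unless ``count_root``; extant taxa
    contribute no extinction event.
    """
    ts_arr = np.asarray(ts, dtype=float)
    te_arr = np.asarray(te, dtype=float)
    extant_arr = np.asarray(extant, dtype=bool)
    K = grid.n_bins
    ts_bins = grid.bin_index(ts_arr)
    B = np.bincount(ts_bins, minlength=K).astype(float)
    if not count_root and ts_arr.size:
        B[ts_bins[int(np.argmax(ts_arr))]] -= 1
    te_dead = te_arr[~extant_arr]
    D = np.bincount(grid.bin_index(te_dead), minlength=K).astype(float) \
        if te_dead.size else np.zeros(K)
    S = grid.lineage_time(ts_arr, te_arr)
    return B, D, S


def bd_loglik_from_stats(B, D, S, lam, mu) -> float:
    """Birth-death log-likelihood from per-bin sufficient statistics."""
    lam = np.asarray(lam, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any((B > 0) & (lam <= 0)) or np.any((D > 0) & (mu <= 0)):
        return -math.inf
    if np.any(lam < 0) or np.any(mu < 0):
        return -math.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        lterm = np.where(B > 0, B * np.log(np.where(lam > 0, lam, 1.0)), 0.0)
        mterm = np.where(D > 0, D * np.log(np.where(mu > 0, mu, 1.0)), 0.0)
    return float(np.sum(lterm + mterm - (lam + mu) * S))


def bd_loglik_piecewise(ts, te, extant, grid: EpochGrid, lam, mu,
                        count_root: bool = False) -> float:
    """Piecewise-constant birth-death log-likelihood of a set of lifespans.

    ``sum_j [ B_j log lambda_j + D_j log mu_j - (lambda_j + mu_j) S_j ]``
    where ``B_j``/``D_j`` count origination/extinction events in bin ``j``
    and ``S_j`` is the lineage-time in the bin.  An event in a bin whose
    corresponding rate is zero yields ``-inf`` (a rejected state).
    """
    B, D, S = bd_sufficient_stats(ts, te, extant, grid, count_root=count_root)
    return bd_loglik_from_stats(B, D, S, lam, mu)


def half_cauchy_logpdf(x, scale: float):
    """Log density of the half-Cauchy distribution on [0, inf)."""
    x_arr = np.asarray(x, dtype=float)
    out = np.where(
        x_arr < 0, -np.inf,
        _LOG_2_OVER_PI + math.log(scale) - np.log(scale ** 2 + x_arr ** 2),
    )
    return float(out) if np.ndim(x) == 0 else out


@dataclass(frozen=True)
class PriorConfig:
    """Priors on the non-hierarchical parameters and the hyper-prior scale.

    Defaults are vague: ``q ~ Gamma(1.01, rate 0.01)``, ``alpha ~
    Exponential(mean 1)``, and half-Cauchy(0, 1) hyper-priors on the rate
    scales.
    """

    q_shape: float = 1.01
    q_rate: float = 0.01
    alpha_mean: float = 1.0
    hyper_scale: float = 1.0


def log_prior(state: ModelState, config: PriorConfig = PriorConfig()) -> float:
    """Joint log prior of rates, preservation parameters and hyper-scales."""
    if state.q <= 0 or state.alpha <= 0 or state.sig_l <= 0 or state.sig_m <= 0:
        return -math.inf
    if np.any(state.lam < 0) or np.any(state.mu < 0):
        return -math.inf
    lp = float(np.sum(half_cauchy_logpdf(state.lam, state.sig_l)))
    lp += float(np.sum(half_cauchy_logpdf(state.mu, state.sig_m)))
    lp += half_cauchy_logpdf(state.sig_l, config.hyper_scale)
    lp += half_cauchy_logpdf(state.sig_m, config.hyper_scale)
    lp += stats.gamma.logpdf(state.q, a=config.q_shape, scale=1.0 / config.q_rate)
    lp += -state.alpha / config.alpha_mean - math.log(config.alpha_mean)
    return lp
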