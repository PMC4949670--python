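"""Metropolis-Hastings sampler for the joint preservation / birth-death model.

One move class is chosen per generation: sliding-window updates of a random
subset of the latent origination/extinction times (reflected at their hard
bounds, so the move stays symmetric), log-scale multiplier updates of the
preservation parameters ``q`` and ``alpha``, of a single per-epoch rate, or
of a hyper-prior scale.  Multiplier proposals ``x' = x * exp(u)`` with
``u ~ U(-m, m)`` carry the Hastings correction ``x'/x``.

Burn-in is not discarded here; downstream summaries drop the first 20% of
the samples of each replicate chain.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihoods import (EpochGrid, ModelState, PriorConfig,
                          bd_loglik_from_stats, bd_sufficient_stats,
                          gamma_category_rates, half_cauchy_logpdf, log_prior,
                          preservation_loglik)
from .occurrences import TaxonSeries

__all__ = ["McmcConfig", "Trace", "init_state", "run_mcmc", "run_replicates"]


@dataclass(frozen=True)
class McmcConfig:
    """Run-length, proposal schedule and tuning constants of one chain.

    ``weights`` gives the probability of each move class per generation:
    ``times`` (sliding-window ts/te update of a random 10% of taxa), ``q``,
    ``alpha``, ``rates`` (one lambda_j or mu_j) and ``hyper`` (one Cauchy
    scale).  ``mult_*`` are multiplier half-widths on the log scale;
    ``window_times`` is the sliding-window half-width in Myr.
    """

    generations: int
    sample_freq: int = 1000
    seed: int = 0
    weights: dict = field(default_factory=lambda: {
        "times": 0.40, "q": 0.15, "alpha": 0.10, "rates": 0.25, "hyper": 0.10})
    window_times: float = 1.5
    frac_taxa: float = 0.10
    mult_q: float = 0.40
    mult_alpha: float = 0.50
    mult_rates: float = 0.75
    mult_hyper: float = 1.00
    k_categories: int = 8
    conditional: bool = True
    store_times: bool = True
    prior: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self):
        if not (self.generations >= self.sample_freq >= 1):
            raise ValueError("need generations >= sample_freq >= 1")


@dataclass
class Trace:
    """Sampled states of one chain.

    ``data`` holds one row per sample (it, posterior, likelihood, prior,
    q, alpha, sig_l, sig_m, lambda_1..K, mu_1..K, root_age); ``ts``/``te``
    are optional (n_samples, n_taxa) matrices of the latent times; ``taxa``
    and ``groups`` describe the dataset columns; ``labels`` the epoch bins.
    """

    data: pd.DataFrame
    labels: tuple[str, ...]
    taxa: tuple[str, ...] = ()
    groups: tuple[str, ...] = ()
    ts: np.ndarray | None = None
    te: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def rate_columns(self, kind: str) -> list[str]:
        prefix = {"origination": "lambda_", "extinction": "mu_"}[kind]
        return [c for c in self.data.columns if c.startswith(prefix)]

    def to_tsv(self, path, include_times: bool | None = None) -> None:
        df = self.data
        include = self.ts is not None if include_times is None else include_times
        if include and self.ts is not None:
            extra = {}
            for i, name in enumerate(self.taxa):
                extra[f"ts_{name}"] = self.ts[:, i]
            for i, name in enumerate(self.taxa):
                extra[f"te_{name}"] = self.te[:, i]
            df = pd.concat([df, pd.DataFrame(extra, index=df.index)], axis=1)
        header = (f"# epochs: {','.join(self.labels)}\n"
                  f"# groups: {','.join(self.groups)}\n")
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Trace":
        with open(path) as fh:
            line1 = fh.readline().strip()
            line2 = fh.readline().strip()
            labels = tuple(line1.split(": ", 1)[1].split(",")) if line1.startswith("#") else ()
            groups = tuple(x for x in line2.split(": ", 1)[1].split(",") if x) \
                if line2.startswith("#") else ()
            df = pd.read_csv(fh, sep="\t")
        ts_cols = [c for c in df.columns if c.startswith("ts_")]
        te_cols = [c for c in df.columns if c.startswith("te_")]
        taxa = tuple(c[3:] for c in ts_cols)
        ts = df[ts_cols].to_numpy() if ts_cols else None
        te = df[te_cols].to_numpy() if te_cols else None
        core = df.drop(columns=ts_cols + te_cols)
        return cls(data=core, labels=labels, taxa=taxa, groups=groups, ts=ts, te=te)


def _dataset_arrays(dataset: list[TaxonSeries]):
    if not dataset:
        raise ValueError("empty dataset")
    n_occ = np.array([t.ages.size for t in dataset], dtype=float)
    hi = np.array([t.ages.max() for t in dataset])
    lo = np.array([t.ages.min() for t in dataset])
    extant = np.array([t.extant for t in dataset], dtype=bool)
    names = tuple(t.genus for t in dataset)
    groups = tuple(t.group for t in dataset)
    return n_occ, lo, hi, extant, names, groups


def init_state(dataset: list[TaxonSeries], grid: EpochGrid,
               rng: np.random.Generator | None = None) -> ModelState:
    """Starting state: lifespans just beyond the observed age ranges.

    ``ts_i = max(ages_i) + eps`` with ``eps ~ U(0.1, 2)`` Myr, ``te_i = 0``
    for extant taxa else ``max(0, min(ages_i) - eps)``; ``q`` starts at
    total occurrences over total initial lifespan; ``alpha = 1``; all
    per-epoch rates at 0.1; hyper-scales at 1.
    """
    rng = np.random.default_rng() if rng is None else rng
    n_occ, lo, hi, extant, _, _ = _dataset_arrays(dataset)
    ts = hi + rng.uniform(0.1, 2.0, size=hi.size)
    if np.isfinite(grid.boundaries[0]):
        ts = np.minimum(ts, grid.boundaries[0])
    te = np.where(extant, 0.0, np.maximum(0.0, lo - rng.uniform(0.1, 2.0, size=lo.size)))
    q = float(n_occ.sum() / (ts - te).sum())
    K = grid.n_bins
    return ModelState(ts=ts, te=te, q=q, alpha=1.0,
                      lam=np.full(K, 0.1), mu=np.full(K, 0.1))


def _reflect(x: np.ndarray, lo, hi) -> np.ndarray:
    """Fold values into [lo, hi] by reflection (symmetric for in-range starts)."""
    lo = np.broadcast_to(np.asarray(lo, dtype=float), x.shape)
    hi = np.broadcast_to(np.asarray(hi, dtype=float), x.shape)
    span = hi - lo
    out = x.copy()
    finite = np.isfinite(span) & (span > 0)
    # reflect at the lower bound only where the interval is half-open
    half = ~np.isfinite(span)
    out[half] = lo[half] + np.abs(out[half] - lo[half])
    y = np.mod(out[finite] - lo[finite], 2 * span[finite])
    out[finite] = lo[finite] + np.where(y <= span[finite], y, 2 * span[finite] - y)
    degenerate = np.isfinite(span) & (span <= 0)
    out[degenerate] = lo[degenerate]
    return out


def run_mcmc(dataset: list[TaxonSeries], grid: EpochGrid, config: McmcConfig,
             sample_prior: bool = False) -> Trace:
    """Sample the joint posterior of the model by Metropolis-Hastings.

    Deterministic for a given ``config.seed``.  With ``sample_prior`` the
    data likelihood (preservation and birth-death terms) is held constant
    and the latent times are not updated, so the chain targets the priors
    alone — used for detailed-balance smoke tests.
    """
    rng = np.random.default_rng(config.seed)
    n_occ, lo, hi, extant, names, groups = _dataset_arrays(dataset)
    n_taxa = n_occ.size
    state = init_state(dataset, grid, rng)
    K = grid.n_bins
    pcfg = config.prior

    weights = dict(config.weights)
    if sample_prior:
        weights["times"] = 0.0
    move_names = ["times", "q", "alpha", "rates", "hyper"]
    w = np.array([max(0.0, weights.get(m, 0.0)) for m in move_names])
    if w.sum() <= 0:
        raise ValueError("all proposal weights are zero")
    cum_w = np.cumsum(w / w.sum())

    cat_rates = gamma_category_rates(state.alpha, config.k_categories)

    def pres_vector(ts, te, q, rates, idx=None):
        if sample_prior:
            return np.zeros(1 if idx is None else len(idx))
        if idx is None:
            return preservation_loglik(n_occ, ts, te, q, rates=rates,
                                       conditional=config.conditional)
        return preservation_loglik(n_occ[idx], ts[idx], te[idx], q, rates=rates,
                                   conditional=config.conditional)

    pres = pres_vector(state.ts, state.te, state.q, cat_rates) \
        if not sample_prior else np.zeros(n_taxa)
    B, D, S = bd_sufficient_stats(state.ts, state.te, extant, grid)
    bd = 0.0 if sample_prior else bd_loglik_from_stats(B, D, S, state.lam, state.mu)
    prior = log_prior(state, pcfg)
    pres_total = float(pres.sum())
    if not np.isfinite(pres_total + bd + prior):
        raise RuntimeError(
            "non-finite posterior at initialization: "
            f"preservation={pres_total}, birth-death={bd}, prior={prior}")

    n_samples = config.generations // config.sample_freq
    cols = (["it", "posterior", "likelihood", "prior", "q", "alpha",
             "sig_l", "sig_m"]
            + [f"lambda_{j + 1}" for j in range(K)]
            + [f"mu_{j + 1}" for j in range(K)] + ["root_age"])
    out = np.empty((n_samples, len(cols)))
    ts_store = np.empty((n_samples, n_taxa)) if config.store_times else None
    te_store = np.empty((n_samples, n_taxa)) if config.store_times else None

    k_move = max(1, int(round(config.frac_taxa * n_taxa)))
    ts_upper = grid.boundaries[0]
    log2pi = math.log(2.0 / math.pi)
    sample_row = 0

    for g in range(config.generations):
        move = int(np.searchsorted(cum_w, rng.random(), side="left"))
        if move == 0:          # latent times, sliding window with reflection
            idx = rng.choice(n_taxa, size=k_move, replace=False)
            prop_ts = state.ts[idx] + rng.uniform(-config.window_times,
                                                  config.window_times, k_move)
            prop_ts = _reflect(prop_ts, hi[idx], ts_upper)
            prop_te = state.te[idx].copy()
            dead = ~extant[idx]
            if dead.any():
                jitter = rng.uniform(-config.window_times, config.window_times,
                                     int(dead.sum()))
                prop_te[dead] = _reflect(state.te[idx][dead] + jitter,
                                         0.0, lo[idx][dead])
            if np.all(prop_ts - prop_te > 0):
                new_ts = state.ts.copy(); new_ts[idx] = prop_ts
                new_te = state.te.copy(); new_te[idx] = prop_te
                pres_new = pres_vector(new_ts, new_te, state.q, cat_rates, idx)
                B2, D2, S2 = bd_sufficient_stats(new_ts, new_te, extant, grid)
                bd_new = bd_loglik_from_stats(B2, D2, S2, state.lam, state.mu)
                delta = float(pres_new.sum() - pres[idx].sum()) + (bd_new - bd)
                if delta >= 0 or math.log(rng.random()) < delta:
                    state.ts, state.te = new_ts, new_te
                    pres[idx] = pres_new
                    pres_total = float(pres.sum())
                    B, D, S, bd = B2, D2, S2, bd_new
        elif move == 1:        # preservation rate q
            u = rng.uniform(-config.mult_q, config.mult_q)
            q_new = state.q * math.exp(u)
            pres_new = pres_vector(state.ts, state.te, q_new, cat_rates)
            dprior = (stats_gamma_logpdf(q_new, pcfg.q_shape, pcfg.q_rate)
                      - stats_gamma_logpdf(state.q, pcfg.q_shape, pcfg.q_rate))
            delta = float(pres_new.sum()) - pres_total + dprior + u
            if delta >= 0 or math.log(rng.random()) < delta:
                state.q = q_new
                pres = pres_new if not sample_prior else pres
                pres_total = float(pres.sum())
                prior += dprior
        elif move == 2:        # gamma shape alpha
            u = rng.uniform(-config.mult_alpha, config.mult_alpha)
            a_new = state.alpha * math.exp(u)
            rates_new = gamma_category_rates(a_new, config.k_categories)
            pres_new = pres_vector(state.ts, state.te, state.q, rates_new)
            dprior = -(a_new - state.alpha) / pcfg.alpha_mean
            delta = float(pres_new.sum()) - pres_total + dprior + u
            if delta >= 0 or math.log(rng.random()) < delta:
                state.alpha = a_new
                cat_rates = rates_new
                pres = pres_new if not sample_prior else pres
                pres_total = float(pres.sum())
                prior += dprior
        elif move == 3:        # one lambda_j or mu_j
            j = int(rng.integers(2 * K))
            vec, sig = (state.lam, state.sig_l) if j < K else (state.mu, state.sig_m)
            jj = j % K
            x = vec[jj]
            u = rng.uniform(-config.mult_rates, config.mult_rates)
            x_new = x * math.exp(u)
            if sample_prior:
                bd_new = 0.0
            else:
                vec_try = vec.copy(); vec_try[jj] = x_new
                bd_new = bd_loglik_from_stats(
                    B, D, S, vec_try if j < K else state.lam,
                    state.mu if j < K else vec_try)
            dprior = (math.log(sig * sig + x * x)
                      - math.log(sig * sig + x_new * x_new))
            delta = (bd_new - bd) + dprior + u
            if delta >= 0 or math.log(rng.random()) < delta:
                vec[jj] = x_new
                bd = bd_new
                prior += dprior
        else:                  # hyper-prior scale
            which_l = rng.random() < 0.5
            sig = state.sig_l if which_l else state.sig_m
            vec = state.lam if which_l else state.mu
            u = rng.uniform(-config.mult_hyper, config.mult_hyper)
            sig_new = sig * math.exp(u)
            old_terms = (np.sum(half_cauchy_logpdf(vec, sig))
                         + half_cauchy_logpdf(sig, pcfg.hyper_scale))
            new_terms = (np.sum(half_cauchy_logpdf(vec, sig_new))
                         + half_cauchy_logpdf(sig_new, pcfg.hyper_scale))
            dprior = float(new_terms - old_terms)
            delta = dprior + u
            if delta >= 0 or math.log(rng.random()) < delta:
                if which_l:
                    state.sig_l = sig_new
                else:
                    state.sig_m = sig_new
                prior += dprior

        if (g + 1) % config.sample_freq == 0:
            # recompute the prior from scratch at record time to avoid drift
            prior = log_prior(state, pcfg)
            lik = pres_total + bd
            out[sample_row] = ([g + 1, lik + prior, lik, prior, state.q,
                                state.alpha, state.sig_l, state.sig_m]
                               + list(state.lam) + list(state.mu)
                               + [float(state.ts.max())])
            if config.store_times:
                ts_store[sample_row] = state.ts
                te_store[sample_row] = state.te
            sample_row += 1

    df = pd.DataFrame(out, columns=cols)
    df["it"] = df["it"].astype(int)
    return Trace(data=df, labels=grid.labels, taxa=names, groups=groups,
                 ts=ts_store, te=te_store)


def stats_gamma_logpdf(x: float, shape: float, rate: float) -> float:
    """Log density of Gamma(shape, rate) with all constants kept."""
    if x <= 0:
        return -math.inf
    return (shape * math.log(rate) - math.lgamma(shape)
            + (shape - 1.0) * math.log(x) - rate * x)


def run_replicates(datasets: list[list[TaxonSeries]], grid: EpochGrid,
                   config: McmcConfig, sample_prior: bool = False) -> list[Trace]:
    """Independent chains on age-randomized replicates, seeds ``seed + i``."""
    traces = []
    for i, dataset in enumerate(datasets):
        cfg = McmcConfig(**{**config.__dict__, "seed": config.seed + i})
        traces.append(run_mcmc(dataset, grid, cfg, sample_prior=sample_prior))
    return traces
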