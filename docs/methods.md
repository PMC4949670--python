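# Methods

## The joint preservation / birth–death model

The analysis unit is the fossil genus. Each genus *i* carries latent
origination and extinction times `ts_i > te_i ≥ 0` on the geological
timescale (Ma, present = 0, increasing into the past); extant genera have
`te_i` pinned at 0. The model has two layers.

**Preservation.** Conditional on its lifespan, the occurrences of genus *i*
form a homogeneous Poisson process (HPP) with rate `q·r_i` per Myr. `q` is
the global preservation rate (expected occurrences per taxon per Myr); the
multipliers `r_i` capture across-taxon heterogeneity and follow a mean-one
gamma with shape `α`, discretized into `K = 8` equal-probability
categories, each represented by its conditional mean (so the multipliers
average exactly 1 and increase with the category index). For a genus with
`n` occurrences and duration `d = ts − te`, category `c` contributes

```
n·log(q_c) − q_c·d − log(1 − exp(−q_c·d)),    q_c = q·r_c
```

and the per-taxon log-likelihood is the log of the equal-weight category
average, computed by log-sum-exp. The last term conditions on the taxon
having been sampled at least once: genera with zero occurrences never enter
a fossil dataset. An unconditioned variant is available
(`conditional=False`) for sensitivity analyses. The HPP (rather than a
hat-shaped occurrence-density profile) is the deliberate choice for sparse
genus-level data; per-epoch preservation rates are out of scope (`q` is
constant through time, heterogeneous across taxa only).

**Diversification.** Lifespans are tied together by a birth–death process
with piecewise-constant rates on a fixed grid of geological epochs
(packaged: the international stratigraphic epochs, Quaternary merged into
one bin). With `B_j`/`D_j` the origination/extinction events falling in
epoch *j* and `S_j` the total lineage-time there,

```
log L_BD = Σ_j [ B_j·log λ_j + D_j·log μ_j − (λ_j + μ_j)·S_j ].
```

Conventions, all chosen because the underlying theory needs a definite
rule and measure-zero ties must break somewhere:

- The single oldest `ts` is the start of the process and contributes no
  λ factor (a birth–death realization begins with one lineage);
  `count_root=True` restores it.
- Epoch membership is half-open: an event exactly on a boundary belongs to
  the younger epoch.
- Extant taxa contribute lineage-time down to 0 Ma and no extinction term.
- An event in an epoch whose corresponding rate is zero yields −∞ (a
  rejected MCMC state), not an exception.

**Priors.** Each `λ_j` and `μ_j` has a half-Cauchy(0, σ) density with the
scales σ_λ, σ_μ estimated alongside everything else under half-Cauchy(0, 1)
hyper-priors — a hierarchical guard against overparameterizing a grid with
~30 epochs. Defaults for the remaining parameters are vague and
configurable: `q ~ Gamma(1.01, rate 0.01)`, `α ~ Exponential(mean 1)`.

## Sampling

A Metropolis–Hastings sampler updates, per generation, one of: a random 10%
of the latent `ts`/`te` (sliding windows, half-width 1.5 Myr, reflected at
the hard bounds `ts ≥ max(ages)`, `0 ≤ te ≤ min(ages)`, so proposals stay
symmetric); `q` or `α`; one `λ_j` or `μ_j`; or a hyper-scale. Positive
parameters move by multipliers `x′ = x·e^u`, `u ~ U(−m, m)`, with Hastings
correction `x′/x`. Default mix: 40% times, 15% q, 10% α, 25% rates, 10%
hyper-scales — chosen for mixing on synthetic data, fully configurable, and
not reported as tuned-to-data since no schedule is canonical. Chains are
deterministic given a seed; replicate datasets run with seeds
`seed + replicate index`. Burn-in is not discarded at run time; pooling
drops the first 20% of each chain's samples, matching standard practice for
this analysis. Traces are tab-separated with a fixed header
(`it, posterior, likelihood, prior, q, alpha, sig_l, sig_m, lambda_1..K,
mu_1..K, root_age`, optional per-taxon `ts_*`/`te_*` columns) and load in
common MCMC viewers.

A prior-sampling mode (`sample_prior=True`) holds the data likelihood
constant and freezes the latent times; the chain then targets the priors
alone, which the test suite verifies by Kolmogorov–Smirnov against the
half-Cauchy and gamma prior CDFs — a detailed-balance smoke test.

## Data preparation

Occurrence downloads are read through a configurable column map (packaged
default covers PBDB-style headers, since column names drift across
versions). Rows without a parsable genus or valid interval are dropped and
counted. Genus-rank records ("Psilophyton sp.") are retained alongside
species-rank ones. The macrofossil filter removes records whose
preservation/organ field matches microfossil keywords (pollen, spore,
cryptospore, …) via a configurable keyword table — the macro/micro split is
standard but no canonical keyword rule exists, so the table is packaged and
editable, and records with an empty organ field are classed "unknown" and
excluded. Vegetation groups (spore-bearing plants, nonflowering seed
plants, angiosperms) come from a supra-generic taxon → group map; extant
status from a packaged, user-editable genus list. Duplicate rows are kept:
the analysis deliberately uses all available records. Dating uncertainty is
handled by drawing each occurrence age uniformly from its `[min_age,
max_age]` interval, independently per replicate (100 replicates by
default), and running an independent chain per replicate.

## The synthetic-data generator

The generator produces datasets under exactly the model above: forward
birth–death simulation from one lineage (epoch-crossing waiting times are
restarted at boundaries, which is exact by memorylessness — no thinning),
gamma-multiplier HPP preservation, removal of zero-occurrence taxa,
truncation of extant lineages at 0 Ma, and exponential-width dating
intervals (mean 12.7 Myr, the empirical mean width of genus-level plant
occurrence data, with the true age uniformly placed inside the interval and
the lower end clipped at 0).

Two switches matter for testing:

- `min_observed` resamples the whole simulation until at least that many
  taxa are observed. Off by default, because the inference does not
  condition on clade survival; tests that need a guaranteed dataset size
  turn it on explicitly.
- `het_categories` draws the preservation multipliers from the
  *discretized* K-category distribution instead of the continuous gamma.
  The continuous default is what real data look like; the discretized mode
  generates from exactly the model the sampler targets and is what the
  posterior-coverage (parameter-recovery) tests use.

What passing the recovery test shows — and what it does not: with
`het_categories=8`, an ~400-taxon, four-epoch dataset at the default run
length covers the generating rates, `q` and `α` with their 95% HPDs, so the
likelihoods, proposals and Hastings corrections are mutually consistent. It
does not show that the eight-category approximation is innocuous for
heavily sampled continuous-gamma data: with ~20+ occurrences per taxon the
per-taxon likelihood in `r` is sharp enough that the octile grid distorts
the joint fit of (`q`, `α`) — we measured the posterior for `q`
concentrating ~18% above truth under continuous-gamma simulation at
`q = 1.5`, mean lifespan ~15 Myr, while the exact continuous-gamma
likelihood recovers it. Real analyses inherit this approximation; its
direction and size depend on the sampling density. Raising `K` reduces the
error as O(K⁻²).

The generator does not emulate: trait- or diversity-dependent rates,
spatial structure, taxonomic error (synonymy, organ-genera duplicating
lineages), or non-uniform age errors — conclusions about those failure
modes cannot be drawn from these tests.

## Posterior summaries

Pooled chains are summarized per epoch by the posterior mean and the 95%
HPD computed as the shortest contiguous window of sorted samples containing
`⌈0.95·n⌉` of them (ties broken at the lowest start index) — empirical and
oracle-checkable, no kernel density. Net diversification `λ − μ` is formed
per posterior sample before summarizing, preserving the correlation of the
two rates. Adjacent epochs differ significantly when the mean of each lies
outside the other's 95% HPD (both directions required). Boundary
comparisons take the two epochs flanking a grid edge; when a named stage
boundary is internal to an epoch, the nearest grid edge is used and the
output flagged (`exact_edge=False`). Fold changes are ratios of posterior
means, oriented along the direction of change. Clade-origin samples take,
per posterior draw, the maximum `ts` over the clade's member taxa.

## Calibration-prior fitting

Five families are fitted to clade-origin samples by maximum likelihood and
ranked by AIC: uniform (sample min/max), normal (mean/SD), log-normal and
gamma on `samples − offset`, and Laplace (median and mean absolute
deviation, density renormalized over the truncated support for reporting).
The offset and the Laplace truncation point default to
`min(samples) − 0.01` Myr rather than being estimated — the profile
likelihood of a free offset is unbounded at the sample minimum — and a
known offset (a hard minimum-age bound) can be supplied explicitly; note
that the default puts the offset at the *sample* minimum, which for
long-tailed samples sits above the distribution's true lower end and
shifts the fitted log-scale parameters accordingly. Offsets are fixed, not
free, so every family counts k = 2 parameters in `AIC = 2k − 2·logL`;
plain AIC is the default and the small-sample correction is available
behind the `aicc` flag (negligible at the n ≥ 10⁴ of intended use). Exports follow the
parameterization of common dating software: log mean / log SD / offset,
shape / scale / offset, or mean / scale / truncation, plus the sample mean
and 95% HPD.

## Numerical choices and problem sizes

Log-space throughout: log-sum-exp for category averages, a two-regime
`log(1 − e^{−x})`, and −∞ (never exceptions) for out-of-support states.
The category means use the Gamma(α+1) CDF identity and are renormalized to
mean exactly 1 to absorb floating-point drift. Tests and the acceptance
script run a deliberately desk-scale version of the analysis — one
replicate of ~400–1000 observed taxa on a four-epoch grid for 200,000
generations (sampling every 100) — which one CPU completes in about two
minutes while leaving the posterior-coverage properties sharp enough to
assert. Full-scale analyses (hundreds of genera over ~30 epochs, 100
replicates × 5×10⁶ generations) use the same code paths through the CLI.

## Known limitations

- The eight-category preservation heterogeneity is an approximation whose
  bias grows with per-taxon sampling density (see above).
- Unobserved taxa are handled only through the per-taxon sampling
  condition; the birth–death layer sees observed taxa alone, which
  understates rates when preservation is poor.
- Extinction is the disappearance of fossil-genera; pseudo-extinction
  (one lineage described under successive names) is indistinguishable.
- The number and placement of rate shifts is fixed by the epoch grid; the
  model does not infer shift times.
- `q` is constant through time; epoch-varying preservation is not modeled.
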