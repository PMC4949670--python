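# paleorates

Bayesian estimation of origination, extinction and preservation rates from
fossil occurrence tables — built for genus-level compilations of the
vascular-plant fossil record, but applicable to any clade with
occurrence-based (not range-based) fossil data.

Paleobiologists who want to know *when* clades radiated or crashed face two
entangled problems: the first and last fossils of a taxon underestimate its
true lifespan, and dating uncertainty smears every occurrence over the
stratigraphic unit it came from. `paleorates` addresses both by jointly
modelling the preservation process and the diversification process, and by
propagating dating uncertainty through replicate analyses. A by-product of
the inference — the posterior distribution of a clade's oldest origination
time — can be fitted with standard distributions and exported as a
calibration prior for molecular dating.

## Model

Each genus *i* has latent origination and extinction times `ts_i > te_i ≥ 0`
(Ma; `te_i = 0` for extant genera). Conditional on its lifespan, its fossil
occurrences are a homogeneous Poisson process with rate `q·r_i`
(occurrences · taxon⁻¹ · Myr⁻¹), where the mean-one multipliers `r_i` follow
a gamma distribution with shape `α`, discretized into eight
equal-probability categories; the likelihood conditions on every included
taxon having been sampled at least once. Lifespans are tied together by a
birth–death process with piecewise-constant rates `λ_j`, `μ_j`
(events · lineage⁻¹ · Myr⁻¹) on the fixed epochs of the stratigraphic
timescale:

```
log L_BD = Σ_j [ B_j log λ_j + D_j log μ_j − (λ_j + μ_j) S_j ]
```

with `B_j`/`D_j` the origination/extinction events in epoch *j* and `S_j`
the lineage-time. Rates get half-Cauchy(0, σ) priors whose scales σ_λ, σ_μ
are estimated from the data (half-Cauchy(0, 1) hyper-priors). Everything is
sampled by Metropolis–Hastings; replicate chains over age-randomized
datasets are pooled after a 20% burn-in. Rates of adjacent epochs are
declared significantly different when the posterior mean of each lies
outside the 95% HPD interval of the other.

## Worked example

Simulate a fossil record with known rates on a four-epoch grid, infer them
back, test the built-in origination crash at the first epoch boundary, and
fit a calibration prior to the clade-origin posterior:

```python
import numpy as np
from paleorates import (EpochGrid, McmcConfig, SimulationTruth,
                        run_mcmc, combine_replicates, rates_through_time,
                        boundary_comparison, clade_origin_samples,
                        select_best, export_calibration)
from paleorates.synthetic import simulate_dataset, table_to_dataset

grid = EpochGrid(np.array([120.0, 80.0, 60.0, 25.0, 0.0]),
                 ("e1", "e2", "e3", "e4"))
truth = SimulationTruth(grid=grid,
                        lam=np.array([0.15, 0.05, 0.10, 0.05]),
                        mu=np.array([0.05, 0.10, 0.03, 0.05]),
                        q=1.5, alpha=1.5, origin=110.0, seed=7,
                        min_observed=300, het_categories=8)
table, histories = simulate_dataset(truth)
dataset = table_to_dataset(table)

trace = run_mcmc(dataset, grid,
                 McmcConfig(generations=50_000, sample_freq=100, seed=1))
pooled = combine_replicates([trace])      # drops the first 20% as burn-in

summary = rates_through_time(pooled, grid)
print(summary.table[["label", "lambda_mean", "mu_mean", "net_mean"]]
      .round(3).to_string(index=False))

comp = boundary_comparison(pooled, grid, 80.0, kind="origination",
                           boundary_name="e1|e2")
print(f"origination across e1|e2: {comp.fold_change:.2f}-fold "
      f"{comp.direction}, significant={comp.significant}")

origin = clade_origin_samples(pooled)
print(export_calibration(select_best(origin)[0]))
```

prints (403 observed taxa, 9563 occurrences):

```
label  lambda_mean  mu_mean  net_mean
   e1        0.135    0.050     0.085
   e2        0.056    0.079    -0.023
   e3        0.103    0.022     0.082
   e4        0.049    0.048     0.002
origination across e1|e2: 2.42-fold decrease, significant=True
# calibration prior specification
family: log_normal
log_mean: -3.357454
log_sd: 1.663622
offset: 109.797049
...
```

The per-epoch posterior means track the generating rates (λ = 0.15, 0.05,
0.10, 0.05; μ = 0.05, 0.10, 0.03, 0.05), the engineered 3-fold origination
drop at 80 Ma is detected as a significant decrease, and the clade-origin
posterior (truth: the oldest origination at ~110 Ma) is summarized as an
offset log-normal ready to use as a dating calibration.

For real data the same pipeline starts from a PBDB-style download:

```sh
paleorates prep --input download.csv --out-prefix prep --n-reps 100 --seed 1
paleorates run --input prep_rep0.csv --generations 5000000 --seed 1 --out rep0.tsv
paleorates fitorigin --samples origins.txt --out prefix
```

`prep` keeps macrofossil records at genus rank (including "sp." records),
assigns the spore-bearing / nonflowering-seed / angiosperm groups from the
supra-generic taxonomy, and draws each occurrence age uniformly from its
dating interval, once per replicate.

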