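"""Shared fixtures: a toy occurrence download and one full recovery run.

The parameter-recovery experiment (simulate a known-truth dataset, run the
sampler at length, pool the chain) is expensive, so it is run once per
session and shared by the sampler and acceptance tests.
"""
from __future__ import annotations

import numpy as np
import pytest

from paleorates.likelihoods import EpochGrid
from paleorates.posterior import combine_replicates
from paleorates.sampler import McmcConfig, run_mcmc
from paleorates.synthetic import SimulationTruth, simulate_dataset, table_to_dataset

TOY_CSV = """\
occurrence_no,accepted_name,accepted_rank,min_ma,max_ma,plant_organ,class,order
1,Psilophyton sp.,genus,410,420,stem,Trimerophytopsida,
2,Quercus alba,species,0.5,2.5,leaf,Magnoliopsida,Fagales
3,Classopollis sp.,genus,150,160,pollen,Pinopsida,
4,Pinus strobus,species,5,15,wood,Pinopsida,Pinales
5,Lepidodendron sp.,genus,300,320,stem,Lycopodiopsida,Lepidodendrales
6,Quercus sp.,genus,10,10,leaf,Magnoliopsida,Fagales
7,Badinterval sp.,genus,120,100,leaf,Magnoliopsida,
8,??,genus,50,60,leaf,,
9,Ginkgo biloba,species,60,80,leaf,Ginkgoopsida,Ginkgoales
10,Osmunda sp.,genus,100,120,frond,Polypodiopsida,Osmundales
"""


@pytest.fixture()
def toy_csv(tmp_path):
    path = tmp_path / "toy_occurrences.csv"
    path.write_text(TOY_CSV)
    return path


RECOVERY_GRID = EpochGrid(np.array([120.0, 80.0, 60.0, 25.0, 0.0]),
                          ("e1", "e2", "e3", "e4"))
RECOVERY_LAM = np.array([0.15, 0.05, 0.10, 0.05])
RECOVERY_MU = np.array([0.05, 0.10, 0.03, 0.05])
RECOVERY_Q = 1.5
RECOVERY_ALPHA = 1.5


def make_recovery_truth(seed: int = 7) -> SimulationTruth:
    """The standard recovery experiment: 4 epochs, >= 300 observed taxa.

    Preservation multipliers are drawn from the 8-category discretized
    heterogeneity distribution so that the generative model matches the
    model the sampler targets (a posterior-coverage check of the
    inference, not of the discretization).
    """
    return SimulationTruth(grid=RECOVERY_GRID, lam=RECOVERY_LAM, mu=RECOVERY_MU,
                           q=RECOVERY_Q, alpha=RECOVERY_ALPHA, origin=110.0,
                           seed=seed, min_observed=300, het_categories=8)


@pytest.fixture(scope="session")
def recovery_run():
    """Simulated dataset plus a 200k-generation chain and its pooled samples."""
    truth = make_recovery_truth()
    table, histories = simulate_dataset(truth)
    dataset = table_to_dataset(table)
    config = McmcConfig(generations=200_000, sample_freq=100, seed=1)
    trace = run_mcmc(dataset, RECOVERY_GRID, config)
    pooled = combine_replicates([trace])
    return {"truth": truth, "table": table, "histories": histories,
            "dataset": dataset, "trace": trace, "pooled": pooled}
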