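"""Tests of the forward birth-death / preservation / dating-noise generator."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paleorates.likelihoods import EpochGrid, bd_loglik_piecewise
from paleorates.synthetic import (SimulationTruth, TrueTaxonHistory,
                                  read_ground_truth, simulate_bd,
                                  simulate_dataset, simulate_preservation,
                                  table_to_dataset, wrap_age_uncertainty,
                                  write_ground_truth)

ONE_BIN_50 = EpochGrid(np.array([50.0, 0.0]))
ONE_BIN_100 = EpochGrid(np.array([100.0, 0.0]))


def _truth(grid, lam, mu, origin, seed, **kw):
    return SimulationTruth(grid=grid, lam=np.atleast_1d(lam),
                           mu=np.atleast_1d(mu), q=1.0, alpha=1.0,
                           origin=origin, seed=seed, **kw)


class TestSimulateBd:
    def test_no_events_single_extant_taxon(self):
        hist = simulate_bd(_truth(ONE_BIN_50, 0.0, 0.0, origin=50.0, seed=1))
        assert len(hist) == 1
        assert hist[0].extant
        assert hist[0].true_ts == 50.0
        assert hist[0].true_te == 0.0

    def test_yule_mean_population_size(self):
        # pure birth at rate 0.1 for 50 Myr: E[N] = e^5 ~ 148.4
        counts = []
        for seed in range(2000):
            hist = simulate_bd(_truth(ONE_BIN_50, 0.1, 0.0, origin=50.0,
                                      seed=seed))
            counts.append(sum(h.extant for h in hist))
        counts = np.asarray(counts, dtype=float)
        expected = math.exp(0.1 * 50.0)
        se = counts.std(ddof=1) / math.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_pure_death_mean_lifespan(self):
        # single taxon dying at rate 0.2 from 100 Ma: mean lifespan ~ 5 Myr
        spans = []
        for seed in range(2000):
            hist = simulate_bd(_truth(ONE_BIN_100, 0.0, 0.2, origin=100.0,
                                      seed=seed))
            assert len(hist) == 1
            spans.append(hist[0].true_ts - hist[0].true_te)
        spans = np.asarray(spans)
        se = spans.std(ddof=1) / math.sqrt(len(spans))
        assert abs(spans.mean() - 5.0) < 3 * se

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            _truth(ONE_BIN_50, -0.1, 0.0, origin=50.0, seed=1)

    def test_deterministic_given_seed(self):
        a = simulate_bd(_truth(ONE_BIN_50, 0.1, 0.05, origin=50.0, seed=9))
        b = simulate_bd(_truth(ONE_BIN_50, 0.1, 0.05, origin=50.0, seed=9))
        assert a == b


class TestSimulatePreservation:
    def _histories(self, n, span=5.0):
        return [TrueTaxonHistory(i, 10.0, 10.0 - span, False)
                for i in range(n)]

    def test_zero_rate_gives_empty_table(self):
        table, _ = simulate_preservation(self._histories(50), q=0.0,
                                         alpha=1.0, seed=0)
        assert table.empty

    def test_truncated_poisson_mean(self):
        # q*d = 5 with negligible heterogeneity: E[n | n>=1] = 5/(1-e^-5)
        table, _ = simulate_preservation(self._histories(2000), q=1.0,
                                         alpha=1e6, seed=4)
        counts = table.groupby("taxon_id").size().to_numpy(dtype=float)
        expected = 5.0 / (1.0 - math.exp(-5.0))
        se = counts.std(ddof=1) / math.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_unconditional_mean_is_q_times_duration(self):
        # law of total expectation over the gamma multipliers, any alpha
        histories = self._histories(4000, span=3.0)
        table, _ = simulate_preservation(histories, q=0.7, alpha=0.6, seed=8)
        total = table.shape[0]  # unobserved taxa contribute zero occurrences
        mean = total / len(histories)
        # Var(n) = qd + (qd)^2 / alpha for a gamma-Poisson mixture
        var = 0.7 * 3 + (0.7 * 3) ** 2 / 0.6
        se = math.sqrt(var / len(histories))
        assert abs(mean - 0.7 * 3.0) < 3 * se

    def test_occurrences_inside_lifespan(self):
        hist = [TrueTaxonHistory(0, 30.0, 12.0, False)]
        table, _ = simulate_preservation(hist, q=2.0, alpha=1.0, seed=1)
        assert np.all((table["age"] >= 12.0) & (table["age"] <= 30.0))

    def test_discretized_multipliers_come_from_category_means(self):
        from paleorates.likelihoods import gamma_category_rates
        hist = self._histories(200)
        _, annotated = simulate_preservation(hist, q=1.0, alpha=1.5, seed=2,
                                             n_categories=8)
        cats = set(np.round(gamma_category_rates(1.5, 8), 12))
        assert {round(h.preservation_multiplier, 12) for h in annotated} <= cats


class TestWrapAgeUncertainty:
    def _table(self, ages):
        import pandas as pd
        return pd.DataFrame({"taxon_id": range(len(ages)),
                             "genus": [f"t{i}" for i in range(len(ages))],
                             "group": "other", "extant": False, "age": ages})

    def test_zero_width_degenerates_to_point(self):
        out = wrap_age_uncertainty(self._table([100.0, 3.0]), 0.0, seed=0)
        np.testing.assert_allclose(out["min_age"], out["age"])
        np.testing.assert_allclose(out["max_age"], out["age"])

    def test_mean_width_matches_exponential(self):
        ages = np.full(10_000, 500.0)        # far from 0, no clipping
        out = wrap_age_uncertainty(self._table(ages), 12.7, seed=5)
        widths = (out["max_age"] - out["min_age"]).to_numpy()
        assert widths.mean() == pytest.approx(12.7, abs=0.4)

    @given(age=st.floats(0.0, 400.0), width=st.floats(0.0, 40.0),
           seed=st.integers(0, 10_000))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_true_age_always_inside_interval(self, age, width, seed):
        out = wrap_age_uncertainty(self._table([age]), width, seed=seed)
        assert out["min_age"].iloc[0] <= age <= out["max_age"].iloc[0]
        assert out["min_age"].iloc[0] >= 0.0


class TestLikelihoodConsistency:
    def test_true_rates_beat_perturbed_rates(self):
        """The generating (lambda, mu) should outscore 0.5x and 2x rescalings
        on nearly every sufficiently large simulated dataset."""
        grid = EpochGrid(np.array([140.0, 60.0, 0.0]))
        lam, mu = np.array([0.12, 0.08]), np.array([0.04, 0.06])
        wins = 0
        n_sets = 20
        for seed in range(n_sets):
            truth = SimulationTruth(grid=grid, lam=lam, mu=mu, q=5.0,
                                    alpha=1.0, origin=130.0, seed=100 + seed,
                                    min_observed=300)
            table, hist = simulate_dataset(truth)
            observed = set(table["taxon_id"])
            ts = np.array([h.true_ts for h in hist if h.taxon_id in observed])
            te = np.array([h.true_te for h in hist if h.taxon_id in observed])
            extant = te == 0.0
            ll_true = bd_loglik_piecewise(ts, te, extant, grid, lam, mu)
            ll_half = bd_loglik_piecewise(ts, te, extant, grid, 0.5 * lam,
                                          0.5 * mu)
            ll_double = bd_loglik_piecewise(ts, te, extant, grid, 2.0 * lam,
                                            2.0 * mu)
            wins += (ll_true > ll_half) and (ll_true > ll_double)
        assert wins >= math.ceil(0.95 * n_sets)


class TestGroundTruthIO:
    def test_histories_round_trip(self, tmp_path):
        truth = _truth(ONE_BIN_50, 0.1, 0.05, origin=50.0, seed=3)
        hist = simulate_bd(truth)
        _, annotated = simulate_preservation(hist, 1.0, 1.0, seed=0)
        path = tmp_path / "truth.csv"
        write_ground_truth(annotated, path)
        assert read_ground_truth(path) == annotated

    def test_simulation_truth_round_trip(self, tmp_path):
        truth = SimulationTruth(grid=ONE_BIN_50, lam=np.array([0.1]),
                                mu=np.array([0.05]), q=1.5, alpha=2.0,
                                origin=45.0, seed=17, mean_width=12.7,
                                min_observed=10, het_categories=8)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = SimulationTruth.from_json(path)
        assert back.q == truth.q and back.seed == truth.seed
        assert back.het_categories == 8
        np.testing.assert_array_equal(back.grid.boundaries,
                                      truth.grid.boundaries)

    def test_dataset_grouping(self):
        truth = _truth(ONE_BIN_50, 0.1, 0.05, origin=50.0, seed=3)
        table, _ = simulate_preservation(simulate_bd(truth), 1.0, 1.0, seed=0)
        dataset = table_to_dataset(table)
        assert sum(t.ages.size for t in dataset) == len(table)
        assert {t.genus for t in dataset} == set(table["genus"])
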