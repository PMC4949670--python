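"""Unit and property tests of the closed-form model components."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from paleorates.likelihoods import (EpochGrid, ModelState,
                                    bd_loglik_piecewise, gamma_category_rates,
                                    half_cauchy_logpdf, log1mexp, log_prior,
                                    preservation_loglik)

ONE_BIN = EpochGrid(np.array([np.inf, 0.0]))
TWO_BIN = EpochGrid(np.array([np.inf, 5.0, 0.0]))


class TestEpochGrid:
    def test_validation(self):
        with pytest.raises(ValueError):
            EpochGrid(np.array([10.0, 5.0]))          # does not end at 0
        with pytest.raises(ValueError):
            EpochGrid(np.array([5.0, 10.0, 0.0]))     # not decreasing

    def test_boundary_event_goes_to_younger_bin(self):
        grid = EpochGrid(np.array([100.0, 50.0, 0.0]))
        assert grid.bin_index(np.array([50.0]))[0] == 1
        assert grid.bin_index(np.array([50.0 + 1e-9]))[0] == 0
        assert grid.bin_index(np.array([0.0]))[0] == 1

    def test_lineage_time_overlaps(self):
        ts = np.array([10.0, 8.0])
        te = np.array([4.0, 0.0])
        np.testing.assert_allclose(TWO_BIN.lineage_time(ts, te), [8.0, 6.0])

    def test_packaged_stratigraphic_grid(self):
        grid = EpochGrid.stratigraphic()
        assert grid.boundaries[0] == 541.0
        assert grid.boundaries[-1] == 0.0
        assert "Lopingian" in grid.labels

    def test_subgrid_keeps_bin_containing_age(self):
        grid = EpochGrid(np.array([300.0, 200.0, 100.0, 0.0]))
        sub = grid.subgrid(150.0)
        np.testing.assert_allclose(sub.boundaries, [200.0, 100.0, 0.0])


class TestGammaCategories:
    def test_single_bin_is_one(self):
        np.testing.assert_allclose(gamma_category_rates(0.37, 1), [1.0])

    def test_vanishing_variance(self):
        assert np.max(np.abs(gamma_category_rates(1e6, 8) - 1.0)) < 1e-2

    def test_matches_quadrature_alpha_one(self):
        # conditional means of x*exp(-x) over the 8 octile bins, mass 1/8 each
        edges = stats.expon.ppf(np.linspace(0, 1, 9))
        oracle = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            val, _ = integrate.quad(lambda x: x * math.exp(-x), lo,
                                    min(hi, 60.0), limit=200)
            oracle.append(val * 8)
        np.testing.assert_allclose(gamma_category_rates(1.0, 8), oracle,
                                   atol=1e-8)

    @given(alpha=st.floats(0.05, 50.0), K=st.integers(2, 16))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_mean_one_and_monotone(self, alpha, K):
        r = gamma_category_rates(alpha, K)
        assert abs(r.mean() - 1.0) < 1e-12
        assert np.all(np.diff(r) > 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            gamma_category_rates(-1.0, 8)
        with pytest.raises(ValueError):
            gamma_category_rates(1.0, 0)


class TestPreservationLoglik:
    def test_closed_form_no_heterogeneity(self):
        got = preservation_loglik(3, 10.0, 0.0, 0.5, K=1)
        expected = 3 * math.log(0.5) - 5.0 - math.log(1 - math.exp(-5.0))
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(-7.07268, abs=1e-5)

    def test_conditioning_vanishes_for_long_lifespans(self):
        n, q, d = 5, 1.2, 400.0
        got = preservation_loglik(n, d, 0.0, q, K=1)
        assert got == pytest.approx(n * math.log(q) - q * d, abs=1e-12)

    def test_unconditioned_variant(self):
        n, q, d = 3, 0.5, 10.0
        got = preservation_loglik(n, d, 0.0, q, K=1, conditional=False)
        assert got == pytest.approx(n * math.log(q) - q * d, abs=1e-12)

    @given(shift=st.floats(0.0, 300.0), n=st.integers(1, 50),
           d=st.floats(0.5, 80.0), q=st.floats(0.05, 5.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_depends_only_on_duration(self, shift, n, d, q):
        base = preservation_loglik(n, d, 0.0, q, alpha=1.3, K=8)
        moved = preservation_loglik(n, d + shift, shift, q, alpha=1.3, K=8)
        assert moved == pytest.approx(base, rel=1e-10)

    def test_k64_converges_to_continuous_gamma(self):
        n, d, q, alpha = 3, 10.0, 0.5, 1.0

        def integrand(r):
            return ((q * r) ** n * math.exp(-q * r * d)
                    / (1 - math.exp(-q * r * d))
                    * stats.gamma.pdf(r, alpha, scale=1 / alpha))

        val, _ = integrate.quad(integrand, 0, np.inf, limit=400)
        got = preservation_loglik(n, d, 0.0, q, alpha=alpha, K=64)
        assert got == pytest.approx(math.log(val), abs=1e-4)

    def test_rejects_unobserved_taxa_and_bad_durations(self):
        with pytest.raises(ValueError):
            preservation_loglik(0, 10.0, 0.0, 0.5, K=1)
        with pytest.raises(ValueError):
            preservation_loglik(2, 5.0, 5.0, 0.5, K=1)

    def test_vector_input_matches_scalar_loop(self):
        n = np.array([1, 4, 9])
        ts = np.array([12.0, 30.0, 7.5])
        te = np.array([2.0, 0.0, 1.0])
        vec = preservation_loglik(n, ts, te, 0.8, alpha=2.0, K=8)
        per = [preservation_loglik(int(a), b, c, 0.8, alpha=2.0, K=8)
               for a, b, c in zip(n, ts, te)]
        np.testing.assert_allclose(vec, per, rtol=1e-12)


class TestBirthDeathLoglik:
    TS = np.array([10.0, 8.0])
    TE = np.array([4.0, 0.0])
    EXTANT = np.array([False, True])

    def test_one_bin_hand_value(self):
        got = bd_loglik_piecewise(self.TS, self.TE, self.EXTANT, ONE_BIN,
                                  [0.1], [0.05])
        expected = math.log(0.1) - 0.1 * 14 + math.log(0.05) - 0.05 * 14
        assert got == pytest.approx(expected, abs=1e-12)

    def test_two_bin_hand_value(self):
        got = bd_loglik_piecewise(self.TS, self.TE, self.EXTANT, TWO_BIN,
                                  [0.1, 0.2], [0.05, 0.05])
        expected = (math.log(0.1) - 0.15 * 8) + (math.log(0.05) - 0.25 * 6)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_grid_refinement_invariance(self):
        rng = np.random.default_rng(11)
        ts = rng.uniform(5, 90, 40)
        te = np.maximum(0.0, ts - rng.exponential(12, 40))
        extant = te == 0.0
        one = bd_loglik_piecewise(ts, te, extant, ONE_BIN, [0.12], [0.07])
        split = EpochGrid(np.array([np.inf, 43.7, 0.0]))
        two = bd_loglik_piecewise(ts, te, extant, split,
                                  [0.12, 0.12], [0.07, 0.07])
        assert two == pytest.approx(one, abs=1e-10)

    def test_single_extant_taxon_has_no_event_terms(self):
        got = bd_loglik_piecewise(np.array([30.0]), np.array([0.0]),
                                  np.array([True]), TWO_BIN,
                                  [0.2, 0.1], [0.05, 0.02])
        assert got == pytest.approx(-(0.25 * 25.0 + 0.12 * 5.0), abs=1e-12)

    def test_event_in_zero_rate_bin_is_minus_inf(self):
        got = bd_loglik_piecewise(self.TS, self.TE, self.EXTANT, ONE_BIN,
                                  [0.1], [0.0])
        assert got == -math.inf


class TestPriors:
    def _state(self, **kw):
        base = dict(ts=np.array([10.0]), te=np.array([0.0]), q=1.0, alpha=1.0,
                    lam=np.array([0.1]), mu=np.array([0.1]),
                    sig_l=1.0, sig_m=1.0)
        base.update(kw)
        return ModelState(**base)

    def test_half_cauchy_at_origin(self):
        assert half_cauchy_logpdf(0.0, 1.0) == pytest.approx(
            math.log(2 / math.pi), abs=1e-12)
        assert half_cauchy_logpdf(-0.5, 1.0) == -math.inf

    def test_negative_rate_gives_minus_inf(self):
        assert log_prior(self._state(lam=np.array([-0.1]))) == -math.inf

    def test_doubling_scale_at_origin_costs_log_two(self):
        lo = self._state(lam=np.array([0.0, 0.0]), sig_l=1.0)
        hi = self._state(lam=np.array([0.0, 0.0]), sig_l=2.0)
        per_lam = ((half_cauchy_logpdf(0.0, 1.0))
                   - (half_cauchy_logpdf(0.0, 2.0)))
        assert per_lam == pytest.approx(math.log(2.0), abs=1e-12)
        diff = log_prior(lo) - log_prior(hi)
        hyper = (half_cauchy_logpdf(1.0, 1.0) - half_cauchy_logpdf(2.0, 1.0))
        assert diff == pytest.approx(2 * math.log(2.0) + hyper, abs=1e-12)

    @given(q=st.floats(0.01, 30.0), alpha=st.floats(0.05, 20.0),
           lam=st.floats(0.0, 5.0), mu=st.floats(0.0, 5.0),
           sig=st.floats(0.05, 10.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_posterior_density_finite_on_support(self, q, alpha, lam, mu, sig):
        state = self._state(q=q, alpha=alpha, lam=np.array([lam]),
                            mu=np.array([mu]), sig_l=sig, sig_m=sig)
        assert np.isfinite(log_prior(state))

    def test_log1mexp_stable_both_regimes(self):
        for x in (1e-9, 0.1, 0.6931, 0.6932, 5.0, 50.0):
            assert log1mexp(x) == pytest.approx(math.log1p(-math.exp(-x)) if x > 1
                                                else math.log(-math.expm1(-x)),
                                                rel=1e-12)
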