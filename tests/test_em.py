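"""EM initialization heuristics and parameter updates."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

from shiftmatch.em import (
    MatchMarginals,
    beta_prior_from_mean,
    expectation,
    fit_frechet,
    initialize_params,
    run_em,
    update_phi,
    update_theta,
)
from shiftmatch.model import (
    DistanceMatrix,
    ModelParams,
    csp_log_density,
    match_log_density,
    noise_log_density,
    solve_omega,
)
from shiftmatch.smc import Ensemble


class TestBetaPrior:
    def test_rescale_branch_keeps_mean(self):
        # mean 0.1, variance_scale 2 -> target sd 0.4 is infeasible for a
        # Beta, so the counts rescale to (1, 9) preserving the mean
        a, b = beta_prior_from_mean(0.1, 2.0)
        assert math.isclose(a / (a + b), 0.1, rel_tol=1e-12)
        assert math.isclose(min(a, b), 1.0)
        assert (a, b) == (1.0, 9.0)

    def test_feasible_variance_solves_moments(self):
        a, b = beta_prior_from_mean(0.5, 0.2)  # sd 0.2, feasible
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert math.isclose(mean, 0.5, rel_tol=1e-12)
        assert math.isclose(math.sqrt(var), 0.2, rel_tol=1e-9)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2])
    def test_invalid_mean_rejected(self, bad):
        with pytest.raises(ValueError):
            beta_prior_from_mean(bad, 1.0)


class TestInitialization:
    def test_fallback_when_no_large_minima(self):
        D = DistanceMatrix(values=np.full((5, 5), 0.5), ndim=2)
        with pytest.warns(UserWarning, match="falling back"):
            p = initialize_params(D, 0.1, max_csp_distance=400.0, variance_scale=2.0)
        assert p.frechet_shape == 1.5
        assert math.isclose(p.mixture_weight, 0.1, rel_tol=1e-9)

    def test_frechet_mle_recovery_from_row_minima(self, rng):
        # row minima drawn from Frechet(2, 8) with sub-threshold noise mixed in
        true = stats.invweibull.rvs(2.0, scale=8.0, size=200, random_state=rng)
        true = np.maximum(true, 3.0)
        noise = rng.uniform(0, 2.9, size=60)
        minima = np.concatenate([true, noise])
        vals = np.tile(minima[:, None], (1, 3)) + np.array([0.0, 5.0, 9.0])
        D = DistanceMatrix(values=vals, ndim=2)
        p = initialize_params(D, 0.1, max_csp_distance=4000.0, variance_scale=2.0)
        assert abs(p.frechet_shape - 2.0) / 2.0 < 0.2
        assert abs(p.frechet_scale - 8.0) / 8.0 < 0.2

    def test_omega_tied_at_dmax(self):
        D = DistanceMatrix(values=np.array([[10.0, 40.0], [5.0, 80.0]]), ndim=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = initialize_params(D, 0.2, max_csp_distance=300.0, variance_scale=1.0)
        from shiftmatch.model import nomatch_log_density

        assert abs(
            float(match_log_density(300.0, p)) - nomatch_log_density(p)
        ) < 1e-12


def make_marginals(p_match, p_csp):
    return MatchMarginals(p_match=np.asarray(p_match, float),
                          p_csp=np.asarray(p_csp, float))


class TestExpectation:
    def _params(self, phi):
        p = ModelParams(
            frechet_shape=1.5, frechet_scale=8.0, mixture_weight=phi,
            nomatch_level=1.0, prior_a=1.0, prior_b=4.0,
            max_csp_distance=400.0, dof=2,
        )
        return p.with_(nomatch_level=solve_omega(p))

    def test_identical_samples_give_binary_frequencies(self):
        decisions = np.tile(np.array([[1, 2, 3]]), (50, 1))  # T=3 -> col 3 = NO_MATCH
        ens = Ensemble(decisions=decisions, log_target=np.zeros(50),
                       log_proposal=np.zeros(50))
        D = DistanceMatrix(values=np.ones((3, 3)), ndim=2)
        marg = expectation(ens, D, self._params(0.2))
        assert set(np.unique(marg.p_match)) <= {0.0, 1.0}
        assert marg.p_match[0, 1] == 1.0 and marg.p_match[2, 3] == 1.0

    def test_phi_zero_gives_zero_csp_responsibility(self):
        decisions = np.zeros((10, 2), dtype=int)
        decisions[:, 1] = 1
        ens = Ensemble(decisions=decisions, log_target=np.zeros(10),
                       log_proposal=np.zeros(10))
        D = DistanceMatrix(values=np.ones((2, 2)), ndim=2)
        marg = expectation(ens, D, self._params(0.0))
        assert np.all(marg.p_csp == 0.0)

    def test_balance_point_gives_half(self):
        p = self._params(0.3)
        # find d where phi*frechet == (1-phi)*chi2 by bisection
        f = lambda d: (math.log(0.3) + csp_log_density(d, 1.5, 8.0)
                       - math.log(0.7) - noise_log_density(d, 2))
        lo, hi = 1.0, 50.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
        d_star = 0.5 * (lo + hi)
        decisions = np.zeros((4, 1), dtype=int)
        ens = Ensemble(decisions=decisions, log_target=np.zeros(4),
                       log_proposal=np.zeros(4))
        D = DistanceMatrix(values=np.array([[d_star]]), ndim=2)
        marg = expectation(ens, D, p)
        assert math.isclose(marg.p_csp[0, 0], 0.5, abs_tol=1e-6)


class TestUpdatePhi:
    def test_uniform_prior_hand_value(self):
        # sum p_csp*p_match = 3, sum p_match = 10, a=b=1 -> phi = 0.3
        p_match = np.zeros((5, 3))
        p_match[:, 0] = 2.0  # artificial masses summing to 10 over targets
        p_csp = np.full((5, 2), 0.3)
        marg = make_marginals(p_match, p_csp)
        assert math.isclose(update_phi(marg, 1.0, 1.0, 0.5), 0.3, rel_tol=1e-12)

    def test_no_matches_keeps_previous(self):
        marg = make_marginals(np.zeros((3, 4)), np.zeros((3, 3)))
        with pytest.warns(UserWarning, match="keeping previous"):
            assert update_phi(marg, 1.0, 9.0, 0.42) == 0.42

    def test_dominating_prior_pins_phi_to_prior_mean(self):
        p_match = np.zeros((4, 3))
        p_match[:, 0] = 1.0
        p_csp = np.ones((4, 2))
        marg = make_marginals(p_match, p_csp)
        phi = update_phi(marg, 100.0, 900.0, 0.5)
        assert abs(phi - 0.1) < 0.01


class TestUpdateTheta:
    def _params(self, shape, scale, phi):
        p = ModelParams(
            frechet_shape=shape, frechet_scale=scale, mixture_weight=phi,
            nomatch_level=1.0, prior_a=1.0, prior_b=4.0,
            max_csp_distance=4000.0, dof=2,
        )
        return p.with_(nomatch_level=solve_omega(p))

    def test_recovery_with_pure_csp(self, rng):
        d = stats.invweibull.rvs(2.0, scale=8.0, size=300, random_state=rng)
        D = DistanceMatrix(values=d[:, None], ndim=2)
        p_match = np.column_stack([np.ones(300), np.zeros(300)])
        marg = make_marginals(p_match, np.ones((300, 1)))
        shape, scale = update_theta(marg, D, self._params(1.5, 5.0, 1.0))
        assert abs(shape - 2.0) / 2.0 < 0.1
        assert abs(scale - 8.0) / 8.0 < 0.1

    def test_single_cell_stays_in_bounds(self):
        D = DistanceMatrix(values=np.array([[12.0]]), ndim=2)
        marg = make_marginals(np.array([[1.0, 0.0]]), np.array([[1.0]]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shape, scale = update_theta(marg, D, self._params(1.5, 8.0, 1.0))
        assert shape >= 1.0 and scale > 0.0

    def test_monotone_improvement(self, rng):
        d = stats.invweibull.rvs(1.5, scale=10.0, size=100, random_state=rng)
        D = DistanceMatrix(values=d[:, None], ndim=2)
        marg = make_marginals(np.column_stack([np.ones(100), np.zeros(100)]),
                              np.ones((100, 1)))
        start = self._params(3.0, 2.0, 0.9)

        def objective(shape, scale):
            trial = start.with_(frechet_shape=shape, frechet_scale=scale)
            return float(np.sum(match_log_density(d, trial)))

        shape, scale = update_theta(marg, D, start)
        assert objective(shape, scale) >= objective(3.0, 2.0) - 1e-9


class TestFitFrechet:
    def test_plain_mle(self, rng):
        d = stats.invweibull.rvs(2.5, scale=4.0, size=2000, random_state=rng)
        shape, scale = fit_frechet(d)
        assert abs(shape - 2.5) / 2.5 < 0.1 and abs(scale - 4.0) / 4.0 < 0.1

    def test_shape_bound_respected(self, rng):
        d = rng.uniform(0.5, 100, size=50)  # nothing like a Frechet
        shape, _ = fit_frechet(d)
        assert shape >= 1.0


class TestRunEm:
    def test_unambiguous_single_match(self, peaklist_factory):
        ref = peaklist_factory([(8.0, 120.0), (9.5, 130.0)])
        tgt = peaklist_factory([(8.0005, 120.005), (9.5005, 129.995)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state, marg, ens = run_em(
                ref, tgt, expected_csp_fraction=0.1, max_csp_distance=2000.0,
                variance_scale=2.0, seed=4,
            )
        assert marg.p_match[0, 0] > 0.99 and marg.p_match[1, 1] > 0.99

    def test_parameter_trajectory_deterministic(self, peaklist_factory, rng):
        shifts = rng.uniform([7.0, 110.0], [9.0, 125.0], size=(12, 2))
        ref = peaklist_factory(shifts)
        tgt = peaklist_factory(shifts + rng.normal(scale=[0.002, 0.02], size=(12, 2)))
        kw = dict(expected_csp_fraction=0.1, max_csp_distance=2000.0,
                  variance_scale=2.0, seed=11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1, m1, _ = run_em(ref, tgt, **kw)
            s2, m2, _ = run_em(ref, tgt, **kw)
        assert s1.param_history == s2.param_history
        np.testing.assert_array_equal(m1.p_match, m2.p_match)

    def test_parameters_stay_in_bounds(self, peaklist_factory, rng):
        shifts = rng.uniform([7.0, 110.0], [9.0, 125.0], size=(15, 2))
        ref = peaklist_factory(shifts)
        tgt = peaklist_factory(shifts + rng.normal(scale=[0.002, 0.02], size=(15, 2)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state, _, _ = run_em(
                ref, tgt, expected_csp_fraction=0.1, max_csp_distance=2000.0,
                variance_scale=2.0, seed=7,
            )
        for rec in state.param_history:
            assert rec["frechet_shape"] >= 1.0
            assert rec["frechet_scale"] > 0.0
            assert 0.0 <= rec["phi"] <= 1.0
            assert rec["omega"] > 0.0
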