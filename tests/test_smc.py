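"""Decision matrix, beam proposals, resampling and the SMC posterior sampler."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from scipy.special import logsumexp

from shiftmatch.model import DistanceMatrix, ModelParams, solve_omega
from shiftmatch.ordering import build_ordering
from shiftmatch.smc import (
    SamplingError,
    SMCConfig,
    beam_proposal,
    build_decision_matrix,
    enumerate_exact_posterior,
    ess_ratio,
    match_frequencies,
    sample_posterior,
    stratified_resample_indices,
)


def params_with_omega(omega=None, **kw):
    defaults = dict(
        frechet_shape=1.5, frechet_scale=8.0, mixture_weight=0.2,
        nomatch_level=1.0, prior_a=1.0, prior_b=4.0,
        max_csp_distance=400.0, dof=2,
    )
    defaults.update(kw)
    p = ModelParams(**defaults)
    return p.with_(nomatch_level=omega if omega is not None else solve_omega(p))


class TestDecisionMatrix:
    def test_one_by_one(self):
        from shiftmatch.model import match_log_density

        p = params_with_omega()
        D = DistanceMatrix(values=np.array([[2.5]]), ndim=2)
        S = build_decision_matrix(D, p)
        assert S.log_s.shape == (1, 2)
        assert math.isclose(S.log_s[0, 0], float(match_log_density(2.5, p)))
        assert math.isclose(S.log_s[0, 1], -math.log(p.nomatch_level))

    def test_row_shares_additive_constant(self):
        from shiftmatch.model import match_log_density

        p = params_with_omega()
        D = DistanceMatrix(values=np.array([[1.0, 5.0, 9.0]]), ndim=2)
        S = build_decision_matrix(D, p)
        log_nm = -math.log(p.nomatch_level)
        for t, d in enumerate([1.0, 5.0, 9.0]):
            assert math.isclose(
                S.log_s[0, t], float(match_log_density(d, p)) + 2 * log_nm
            )
        assert math.isclose(S.log_s[0, 3], 3 * log_nm)

    def test_two_by_two_hand_products(self):
        from shiftmatch.model import match_log_density

        p = params_with_omega()
        vals = np.array([[1.0, 4.0], [2.0, 8.0]])
        S = build_decision_matrix(DistanceMatrix(values=vals, ndim=2), p)
        log_nm = -math.log(p.nomatch_level)
        for r in range(2):
            for t in range(2):
                expected = float(match_log_density(vals[r, t], p)) + log_nm
                assert math.isclose(S.log_s[r, t], expected)


class TestEssRatio:
    def test_equal_weights(self):
        assert math.isclose(ess_ratio(np.zeros(50)), 1.0)

    def test_one_hot(self):
        lw = np.full(100, -np.inf)
        lw[3] = 0.0
        assert math.isclose(ess_ratio(lw), 0.01)

    def test_hand_value(self):
        lw = np.log(np.array([0.7, 0.3]))
        assert math.isclose(ess_ratio(lw), 1.0 / (2 * 0.58), rel_tol=1e-9)

    def test_degenerate_errors(self):
        with pytest.raises(SamplingError):
            ess_ratio(np.array([-np.inf, -np.inf]))


class TestStratifiedResample:
    def test_uniform_weights_draw_each_once(self, rng):
        idx = stratified_resample_indices(np.ones(10) / 10, rng)
        assert sorted(idx.tolist()) == list(range(10))

    def test_degenerate_weight_vector(self, rng):
        idx = stratified_resample_indices(np.array([1.0, 0.0]), rng)
        assert idx.tolist() == [0, 0]

    def test_copy_counts_match_weights(self, rng):
        w = np.array([0.5, 0.3, 0.2])
        n_rep = 4000
        counts = np.zeros(3)
        for _ in range(n_rep):
            idx = stratified_resample_indices(w, rng)
            counts += np.bincount(idx, minlength=3)
        n = 3
        for i in range(3):
            expect = n_rep * n * w[i]
            se = math.sqrt(n_rep * n * w[i] * (1 - w[i]))
            assert abs(counts[i] - expect) < 3 * se + 3


def brute_force_proposal(S, rows, used, first_row_idx=0):
    """Enumerate Eq.-20 exactly: sum of completions per first decision."""
    T = S.n_tgt
    r0 = rows[0]
    weights = {}
    for combo in itertools.product(range(T + 1), repeat=len(rows)):
        tgts = [t for t in combo if t != T]
        if len(set(tgts)) != len(tgts) or any(t in used for t in tgts):
            continue
        logw = sum(S.log_s[r, t] for r, t in zip(rows, combo))
        weights.setdefault(combo[0], []).append(logw)
    return {a: logsumexp(v) for a, v in weights.items()}


class TestBeamProposal:
    def _instance(self, rng, R=3, T=3):
        vals = rng.uniform(0.2, 30, size=(R, T))
        p = params_with_omega()
        return DistanceMatrix(values=vals, ndim=2), p

    def test_last_row_collapses_to_row_entries(self, rng):
        D, p = self._instance(rng)
        S = build_decision_matrix(D, p)
        sets, _ = build_ordering(D, p, prob_ratio=1e9)
        rows = [2]
        avail, prob = beam_proposal(S, rows, 0, width=100, candidate_sets=sets)
        logw = np.array([S.log_s[2, a] for a in avail])
        expected = np.exp(logw - logsumexp(logw))
        np.testing.assert_allclose(prob, expected / expected.sum(), atol=1e-12)

    def test_wide_beam_equals_enumeration(self, rng):
        for _ in range(5):
            D, p = self._instance(rng)
            S = build_decision_matrix(D, p)
            sets, _ = build_ordering(D, p, prob_ratio=1e9)
            # force every target to be a candidate of every row for the oracle
            if any(len(s.targets) < D.n_tgt for s in sets):
                continue
            rows = [0, 1, 2]
            avail, prob = beam_proposal(S, rows, 0, width=10_000, candidate_sets=sets)
            oracle = brute_force_proposal(S, rows, set())
            logw = np.array([oracle[a] for a in avail])
            expected = np.exp(logw - logsumexp(logw))
            np.testing.assert_allclose(prob, expected / expected.sum(), rtol=1e-8)

    def test_width_one_is_greedy_completion(self):
        # hand-set decision matrix: 2 rows, 2 targets
        p = params_with_omega()
        D = DistanceMatrix(values=np.array([[0.5, 6.0], [0.6, 5.0]]), ndim=2)
        S = build_decision_matrix(D, p)
        sets, _ = build_ordering(D, p, prob_ratio=1e9)
        avail, prob = beam_proposal(S, [0, 1], 0, width=1, candidate_sets=sets)
        # width-1 lookahead keeps only the single best completion per decision
        best_completion = {}
        for a in avail:
            used = {a} if a != 2 else set()
            cands = [t for t in sets[1].targets if t not in used] + [2]
            best_completion[a] = S.log_s[0, a] + max(S.log_s[1, t] for t in cands)
        logw = np.array([best_completion[a] for a in avail])
        expected = np.exp(logw - logsumexp(logw))
        np.testing.assert_allclose(prob, expected / expected.sum(), rtol=1e-9)


class TestSamplePosterior:
    def test_dominated_decision_all_nomatch(self):
        p = params_with_omega()
        D = DistanceMatrix(values=np.array([[4 * p.max_csp_distance]]), ndim=2)
        sets, order = build_ordering(D, p)
        ens = sample_posterior(D, p, order, sets, SMCConfig(min_particles=64), seed=3)
        assert np.all(ens.decisions == 1)  # T == 1 encodes NO_MATCH

    def test_matches_enumeration_on_2x2(self, rng):
        p = params_with_omega()
        D = DistanceMatrix(values=rng.uniform(0.5, 20, size=(2, 2)), ndim=2)
        sets, order = build_ordering(D, p)
        ens = sample_posterior(D, p, order, sets, SMCConfig(min_particles=5000), seed=9)
        exact = enumerate_exact_posterior(D, p)
        counts = Counter(map(tuple, ens.decisions.tolist()))
        n = ens.n_particles
        tv = 0.5 * sum(abs(counts.get(k, 0) / n - q) for k, q in exact.items())
        tv += 0.5 * sum(c / n for k, c in counts.items() if k not in exact)
        assert tv < 0.05

    def test_seed_determinism(self, rng):
        p = params_with_omega()
        D = DistanceMatrix(values=rng.uniform(0.5, 20, size=(4, 4)), ndim=2)
        sets, order = build_ordering(D, p)
        e1 = sample_posterior(D, p, order, sets, SMCConfig(min_particles=128), seed=17)
        e2 = sample_posterior(D, p, order, sets, SMCConfig(min_particles=128), seed=17)
        np.testing.assert_array_equal(e1.decisions, e2.decisions)
        np.testing.assert_allclose(e1.log_target, e2.log_target)

    def test_exclusivity_invariant(self, rng):
        p = params_with_omega()
        for _ in range(3):
            D = DistanceMatrix(values=rng.uniform(0.5, 25, size=(5, 4)), ndim=2)
            sets, order = build_ordering(D, p)
            ens = sample_posterior(D, p, order, sets, SMCConfig(min_particles=256), seed=5)
            T = D.n_tgt
            for row in ens.decisions:
                matched = row[row < T]
                assert len(set(matched.tolist())) == len(matched)

    def test_weight_bookkeeping_audit(self, rng):
        p = params_with_omega()
        D = DistanceMatrix(values=rng.uniform(0.5, 20, size=(4, 4)), ndim=2)
        sets, order = build_ordering(D, p)
        ens = sample_posterior(D, p, order, sets, SMCConfig(min_particles=128), seed=23)
        S = build_decision_matrix(D, p)
        for i in range(ens.n_particles):
            part = ens.particle(i)
            recomputed = sum(S.log_s[r, t] for r, t in enumerate(part.decisions))
            assert math.isclose(part.log_target, recomputed, rel_tol=1e-12)
            assert math.isclose(
                part.log_weight, part.log_target - part.log_proposal, rel_tol=1e-12
            )

    def test_match_frequencies_are_row_normalized(self, rng):
        p = params_with_omega()
        D = DistanceMatrix(values=rng.uniform(0.5, 20, size=(3, 3)), ndim=2)
        sets, order = build_ordering(D, p)
        ens = sample_posterior(D, p, order, sets, SMCConfig(min_particles=128), seed=2)
        freq = match_frequencies(ens.decisions, D.n_tgt)
        np.testing.assert_allclose(freq.sum(axis=1), 1.0, atol=1e-12)
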