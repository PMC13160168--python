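"""Sequential Monte Carlo sampling of matching matrices.

A complete matching between R reference and T target peaks is encoded as
a decision vector: one decision per reference peak, either a target index
or NO_MATCH, with no target used twice.  Particles make these decisions
in the cluster-contiguous order produced by :mod:`shiftmatch.ordering`,
drawing each decision from a lookahead (beam-search) proposal that
approximates the partial partition function over the remaining rows of
the cluster, and accumulate importance weights as the ratio of the
target likelihood to the proposal probability.

After the last decision of every cluster the effective-sample-size (ESS)
ratio is checked: at or above the threshold the ensemble is stratified-
resampled and sampling continues; below it the cluster's decisions are
discarded, the beam width is escalated fivefold, and the cluster is
retried.  After a full pass a second independent ensemble is drawn and
the per-pair marginal frequencies compared; any discrepancy above the
tolerance doubles the particle count and repeats.  When the check passes
the two ensembles are merged.

In the decision arrays the value ``T`` (one past the last target index)
encodes NO_MATCH.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .model import DistanceMatrix, ModelParams, match_log_density, nomatch_log_density
from .ordering import CandidateSet, OrderingResult

__all__ = [
    "DecisionMatrix",
    "Particle",
    "Ensemble",
    "SMCConfig",
    "SamplingError",
    "build_decision_matrix",
    "beam_proposal",
    "ess_ratio",
    "stratified_resample_indices",
    "stratified_resample",
    "sample_posterior",
    "match_frequencies",
    "enumerate_exact_posterior",
]

logger = logging.getLogger(__name__)


class SamplingError(RuntimeError):
    """Raised when the sampler cannot produce a usable ensemble."""


@dataclass(frozen=True)
class DecisionMatrix:
    """R×(T+1) log decision-likelihood matrix; column T is NO_MATCH.

    ``log_s[r, t]`` is the log likelihood of the whole row r of D under
    the decision "r matches t": the matched density at D[r, t] times the
    non-match density for every other target.  ``log_s[r, T]`` is the
    all-non-match product.  Availability (columns consumed by earlier
    decisions) is tracked per particle in the sampler, not here.
    """

    log_s: np.ndarray

    @property
    def n_ref(self) -> int:
        return self.log_s.shape[0]

    @property
    def n_tgt(self) -> int:
        return self.log_s.shape[1] - 1


@dataclass
class Particle:
    """One sampled decision set with its importance bookkeeping."""

    decisions: np.ndarray  # (R,) int; T = NO_MATCH, -1 = undecided
    log_target: float
    log_proposal: float

    @property
    def log_weight(self) -> float:
        return self.log_target - self.log_proposal


@dataclass
class Ensemble:
    """A weighted particle sample over decision sets (array-of-structs layout).

    ``decisions`` is (N, R) int with value T for NO_MATCH; ``log_target``
    and ``log_proposal`` are cumulative per-particle log likelihood /
    proposal sums; ``log_weight_anchor`` is the value of
    ``log_target - log_proposal`` at the last resampling, so the current
    (unnormalized) log weight is their difference.
    """

    decisions: np.ndarray
    log_target: np.ndarray
    log_proposal: np.ndarray
    log_weight_anchor: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.log_weight_anchor is None:
            self.log_weight_anchor = np.zeros_like(self.log_target)

    @property
    def n_particles(self) -> int:
        return self.decisions.shape[0]

    @property
    def log_weights(self) -> np.ndarray:
        return self.log_target - self.log_proposal - self.log_weight_anchor

    def particle(self, i: int) -> Particle:
        return Particle(
            decisions=self.decisions[i].copy(),
            log_target=float(self.log_target[i]),
            log_proposal=float(self.log_proposal[i]),
        )


@dataclass(frozen=True)
class SMCConfig:
    """Sampler settings.

    ``ess_threshold``, ``freq_tolerance`` and the fivefold width
    escalation follow the published procedure; the particle floor, the
    starting beam width and the width cap are robustness settings.
    """

    min_particles: int = 64
    beam_width: int = 1000
    beam_width_cap: int = 25_000
    ess_threshold: float = 0.2
    freq_tolerance: float = 0.1
    max_doublings: int = 8


def build_decision_matrix(D: DistanceMatrix, params: ModelParams) -> DecisionMatrix:
    """Row-decision log likelihoods from the distance matrix and parameters."""
    T = D.n_tgt
    log_nm = nomatch_log_density(params)
    log_match = match_log_density(D.values, params)
    log_s = np.empty((D.n_ref, T + 1))
    log_s[:, :T] = log_match + (T - 1) * log_nm
    log_s[:, T] = T * log_nm
    return DecisionMatrix(log_s=log_s)


def ess_ratio(log_weights: np.ndarray) -> float:
    """Effective-sample-size ratio (sum w)^2 / (N sum w^2), from log weights."""
    lw = np.asarray(log_weights, dtype=float)
    if lw.size == 0 or not np.any(np.isfinite(lw)):
        raise SamplingError("degenerate ensemble: no particle has finite weight")
    m = lw.max()
    w = np.exp(lw - m)
    return float(w.sum() ** 2 / (lw.size * np.sum(w ** 2)))


def stratified_resample_indices(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Stratified resampling: one uniform draw per stratum [j/N, (j+1)/N)."""
    p = np.asarray(weights, dtype=float)
    p = p / p.sum()
    n = p.size
    u = (np.arange(n) + rng.random(n)) / n
    return np.searchsorted(np.cumsum(p), u, side="right").clip(max=n - 1)


def stratified_resample(ensemble: Ensemble, rng: np.random.Generator) -> Ensemble:
    """Resample an ensemble to uniform weights via stratified resampling."""
    lw = ensemble.log_weights
    w = np.exp(lw - lw.max())
    idx = stratified_resample_indices(w, rng)
    out = Ensemble(
        decisions=ensemble.decisions[idx].copy(),
        log_target=ensemble.log_target[idx].copy(),
        log_proposal=ensemble.log_proposal[idx].copy(),
    )
    out.log_weight_anchor = out.log_target - out.log_proposal
    return out


def _completion_logZ(
    log_s: np.ndarray,
    rows: list[int],
    cands: dict[int, np.ndarray],
    used: frozenset[int],
    width: int,
    n_tgt: int,
) -> tuple[float, bool]:
    """Beam-search estimate of the partition function over ``rows``.

    Sums the likelihoods of partial decision sets over ``rows`` (each
    row branching over its candidate targets plus NO_MATCH, respecting
    exclusivity against ``used`` and along each beam), keeping the
    ``width`` highest-likelihood beams after each row expansion.  Returns
    the log-sum and whether any pruning occurred; without pruning the
    estimate is the exact candidate-restricted partition function.
    Pruning uses a stable sort on likelihood, so ties break on beam
    generation order (lexicographic in the decision path) — deterministic.
    """
    if not rows:
        return 0.0, False
    rel = sorted({int(t) for r in rows for t in cands[r]})
    col = {t: i for i, t in enumerate(rel)}
    n_rel = len(rel)
    logL = np.zeros(1)
    bused = np.zeros((1, n_rel), dtype=bool)
    for t in used:
        if t in col:
            bused[0, col[t]] = True
    truncated = False
    for r in rows:
        cl = np.asarray([int(t) for t in cands[r]], dtype=int)
        B = logL.size
        if cl.size:
            cols = np.array([col[t] for t in cl])
            branchL = logL[:, None] + log_s[r, cl][None, :]  # (B, k)
            branchL[bused[:, cols]] = -np.inf
            branch_used = np.repeat(bused, cl.size, axis=0)
            branch_used[np.arange(B * cl.size), np.tile(cols, B)] = True
            allL = np.concatenate([branchL.ravel(), logL + log_s[r, n_tgt]])
            all_used = np.vstack([branch_used, bused])
        else:
            allL = logL + log_s[r, n_tgt]
            all_used = bused
        valid = allL > -np.inf
        allL, all_used = allL[valid], all_used[valid]
        if allL.size > width:
            sel = np.argsort(-allL, kind="stable")[:width]
            allL, all_used = allL[sel], all_used[sel]
            truncated = True
        logL, bused = allL, all_used
    return float(logsumexp(logL)), truncated


def _candidate_proposal(
    log_s: np.ndarray,
    rows: list[int],
    cands: dict[int, np.ndarray],
    mask: frozenset[int],
    width: int,
    n_tgt: int,
    cache: dict | None = None,
) -> tuple[list[int], np.ndarray, bool]:
    """Lookahead proposal weights over the candidate decisions of one row.

    The available decisions for ``rows[0]`` are its candidate targets not
    in ``mask`` plus NO_MATCH (always last).  Each decision's weight is
    its row likelihood times the beam partition function over the
    remaining rows of the cluster with that decision's target consumed,
    so the proposal approximates the conditional target distribution
    over the cluster (exactly, when no beam was truncated).
    """
    r0, rest = rows[0], rows[1:]
    avail = [int(t) for t in cands[r0] if t not in mask] + [n_tgt]
    logw = np.empty(len(avail))
    truncated = False
    rest_key = tuple(rest)
    rel_rest = {int(t) for r in rest for t in cands[r]}
    for i, a in enumerate(avail):
        used = mask | {a} if a != n_tgt else mask
        key = (rest_key, frozenset(used & rel_rest)) if cache is not None else None
        if key is not None and key in cache:
            logz, trunc = cache[key]
        else:
            logz, trunc = _completion_logZ(log_s, rest, cands, used, width, n_tgt)
            if key is not None:
                cache[key] = (logz, trunc)
        truncated = truncated or trunc
        logw[i] = log_s[r0, a] + logz
    return avail, logw, truncated


def beam_proposal(
    S: DecisionMatrix,
    cluster_rows: list[int],
    position: int,
    width: int,
    candidate_sets: list[CandidateSet],
    used_targets: frozenset[int] = frozenset(),
) -> tuple[list[int], np.ndarray]:
    """Proposal distribution over the available decisions of one row.

    ``cluster_rows[position]`` is the row being decided; rows after it in
    the cluster contribute lookahead mass through the beam search.
    Returns (decisions, probabilities); decisions are the row's available
    candidate targets with ``S.n_tgt`` standing for NO_MATCH, which is
    always available.
    """
    if width < 1:
        raise ValueError("beam width must be >= 1")
    rows = [int(r) for r in cluster_rows[position:]]
    cands = {r: np.asarray(candidate_sets[r].targets, dtype=int) for r in rows}
    avail, logw, _ = _candidate_proposal(
        S.log_s, rows, cands, frozenset(used_targets), width, S.n_tgt
    )
    assert avail, "NO_MATCH is always available"
    p = np.exp(logw - logsumexp(logw))
    return avail, p / p.sum()


def match_frequencies(decisions: np.ndarray, n_tgt: int) -> np.ndarray:
    """(R, T+1) empirical match frequencies from an (N, R) decision array."""
    n, R = decisions.shape
    freq = np.empty((R, n_tgt + 1))
    for r in range(R):
        freq[r] = np.bincount(decisions[:, r], minlength=n_tgt + 1) / n
    return freq


def _sample_pass(
    S: DecisionMatrix,
    candidate_sets: list[CandidateSet],
    ordering: OrderingResult,
    n_particles: int,
    config: SMCConfig,
    width0: int,
    rng_prop: np.random.Generator,
    rng_res: np.random.Generator,
) -> tuple[Ensemble, int]:
    """One full SMC pass over all clusters; returns ensemble and final width."""
    R, T = S.n_ref, S.n_tgt
    N = n_particles
    decisions = np.full((N, R), -1, dtype=np.int64)
    used = np.zeros((N, T), dtype=bool)
    log_target = np.zeros(N)
    log_proposal = np.zeros(N)
    anchor = np.zeros(N)
    width = width0
    log_s = S.log_s
    cand_arr = [np.asarray(candidate_sets[r].targets, dtype=int) for r in range(R)]

    for cluster in ordering.clusters:
        snap = (decisions.copy(), used.copy(), log_target.copy(),
                log_proposal.copy(), anchor.copy())
        while True:
            truncated_any = False
            completion_cache: dict = {}
            for pos, r in enumerate(cluster):
                remaining = [int(rr) for rr in cluster[pos:]]
                relevant = np.unique(np.concatenate([cand_arr[rr] for rr in remaining]
                                                    + [np.empty(0, dtype=int)]))
                # group particles sharing the relevant part of the mask so
                # each distinct prefix pays for one beam search; the
                # availability of non-relevant targets is applied per
                # particle below (it does not change the lookahead)
                groups: dict[bytes, list[int]] = {}
                if relevant.size:
                    sub = used[:, relevant]
                    for p in range(N):
                        groups.setdefault(sub[p].tobytes(), []).append(p)
                else:
                    groups[b""] = list(range(N))
                cands = {rr: cand_arr[rr] for rr in remaining}
                for key, members in groups.items():
                    mask = frozenset(
                        int(t) for t in relevant[np.frombuffer(key, dtype=bool)]
                    ) if relevant.size else frozenset()
                    avail, logw, trunc = _candidate_proposal(
                        log_s, remaining, cands, mask, width, T,
                        cache=completion_cache,
                    )
                    truncated_any = truncated_any or trunc
                    p = np.exp(logw - logsumexp(logw))
                    p /= p.sum()
                    m = len(members)
                    members_arr = np.asarray(members)
                    cum = np.cumsum(p)
                    draws = np.searchsorted(
                        cum, rng_prop.random(m), side="right"
                    ).clip(max=len(avail) - 1)
                    choice = np.asarray(avail, dtype=np.int64)[draws]
                    decisions[members_arr, r] = choice
                    hit = choice < T
                    used[members_arr[hit], choice[hit]] = True
                    log_proposal[members_arr] += np.log(p[draws])
                    log_target[members_arr] += log_s[r, choice]
            lw = log_target - log_proposal - anchor
            ess = ess_ratio(lw)
            if ess < config.ess_threshold and not truncated_any:
                # the beam enumerated every completion, so the low ESS
                # reflects cross-cluster competition for targets, which a
                # wider beam cannot change; resample anyway (unbiased,
                # higher variance) and let the end-of-pass frequency
                # check grow N if the marginals are unstable
                logger.info(
                    "cluster %s: ESS ratio %.3f with exhaustive beam; "
                    "resampling without escalation", cluster[:3], ess,
                )
            if ess >= config.ess_threshold or not truncated_any:
                w = np.exp(lw - lw.max())
                idx = stratified_resample_indices(w, rng_res)
                decisions = decisions[idx].copy()
                used = used[idx].copy()
                log_target = log_target[idx].copy()
                log_proposal = log_proposal[idx].copy()
                anchor = log_target - log_proposal
                break
            logger.info("cluster %s: ESS ratio %.3f < %.2f, widening beam %d -> %d",
                        cluster[:3], ess, config.ess_threshold, width, width * 5)
            decisions, used, log_target, log_proposal, anchor = (
                snap[0].copy(), snap[1].copy(), snap[2].copy(),
                snap[3].copy(), snap[4].copy())
            width *= 5
            if width > config.beam_width_cap:
                raise SamplingError(
                    "proposal failure - beam width cap exceeded; "
                    "check peak lists/parameters"
                )
    ens = Ensemble(decisions=decisions, log_target=log_target,
                   log_proposal=log_proposal)
    ens.log_weight_anchor = log_target - log_proposal
    return ens, width


def sample_posterior(
    D: DistanceMatrix,
    params: ModelParams,
    ordering: OrderingResult,
    candidate_sets: list[CandidateSet],
    config: SMCConfig = SMCConfig(),
    seed: int | np.random.SeedSequence = 0,
) -> Ensemble:
    """Draw an ensemble of complete matchings from the posterior.

    The particle count starts at max(R, ``config.min_particles``).  Each
    pass draws two independent ensembles; if any reference–target
    marginal frequency differs by more than ``config.freq_tolerance``
    between them the particle count is doubled and the pass repeated,
    otherwise the two ensembles are merged and returned (uniform weights,
    both having been resampled at the last cluster).
    """
    S = build_decision_matrix(D, params)
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    n = max(D.n_ref, config.min_particles)
    for doubling in range(config.max_doublings + 1):
        s_prop, s_res = ss.spawn(2)
        rng_p1, rng_p2 = (np.random.default_rng(s) for s in s_prop.spawn(2))
        rng_r1, rng_r2 = (np.random.default_rng(s) for s in s_res.spawn(2))
        ens1, w1 = _sample_pass(S, candidate_sets, ordering, n, config,
                                config.beam_width, rng_p1, rng_r1)
        ens2, _ = _sample_pass(S, candidate_sets, ordering, n, config,
                               w1, rng_p2, rng_r2)
        f1 = match_frequencies(ens1.decisions, D.n_tgt)
        f2 = match_frequencies(ens2.decisions, D.n_tgt)
        dmax = float(np.abs(f1 - f2).max())
        if dmax <= config.freq_tolerance:
            merged = Ensemble(
                decisions=np.vstack([ens1.decisions, ens2.decisions]),
                log_target=np.concatenate([ens1.log_target, ens2.log_target]),
                log_proposal=np.concatenate([ens1.log_proposal, ens2.log_proposal]),
            )
            merged.log_weight_anchor = merged.log_target - merged.log_proposal
            return merged
        logger.info("marginal frequency discrepancy %.3f > %.2f, doubling N to %d",
                    dmax, config.freq_tolerance, 2 * n)
        n *= 2
        ss = ss.spawn(1)[0]
    raise SamplingError(
        f"sample size did not stabilize after {config.max_doublings} doublings"
    )


def enumerate_exact_posterior(
    D: DistanceMatrix, params: ModelParams
) -> dict[tuple[int, ...], float]:
    """Exact posterior over all complete matchings by brute-force enumeration.

    Enumerates every decision vector (all partial injections of rows into
    targets, NO_MATCH allowed everywhere) and normalizes the products of
    row-decision likelihoods.  Only feasible for small R, T; used as the
    independent oracle for the sampler.
    """
    S = build_decision_matrix(D, params)
    R, T = S.n_ref, S.n_tgt
    if R > 6 or T > 6:
        raise ValueError("enumeration oracle is for small instances only")
    results: dict[tuple[int, ...], float] = {}
    for combo in itertools.product(range(T + 1), repeat=R):
        tgts = [t for t in combo if t != T]
        if len(set(tgts)) != len(tgts):
            continue
        results[combo] = sum(S.log_s[r, t] for r, t in enumerate(combo))
    logz = logsumexp(np.array(list(results.values())))
    return {k: float(np.exp(v - logz)) for k, v in results.items()}
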