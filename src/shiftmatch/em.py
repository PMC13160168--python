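"""Expectation–maximization over the likelihood-model parameters.

The matched-pair mixture has unknowns theta = (Fréchet shape, scale),
the mixture weight phi, and the non-match level omega.  EM alternates:

* E step — sample the matching-matrix posterior at the current
  parameters (:func:`shiftmatch.smc.sample_posterior`) and summarize it
  as marginal match frequencies ``p_match`` and per-cell CSP
  responsibilities ``p_csp``;
* M step — a conjugate Beta MAP update for phi, a bounded numerical
  maximization of the expected matched log density for theta (warm-
  started from the previous iterate), and the closed-form omega that
  re-ties the matched and non-matched densities at Dmax.

Initialization follows the row-minimum heuristic: the smallest distance
in each row, values below ``init_min_distance`` removed (those are
noise-regime matches), and a shape-bounded Fréchet fit to the survivors.
The Beta prior on phi is built from the user's expected CSP fraction
(its mean) with a standard deviation of twice the mean times a
user-adjustable variance scale, rescaled to keep both pseudo-counts at
or above 1 while preserving the mean.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .model import (
    DistanceMatrix,
    ModelParams,
    compute_distance_matrix,
    csp_log_density,
    match_log_density,
    solve_omega,
)
from .ordering import build_ordering
from .peaklist import PeakList
from .smc import (
    Ensemble,
    SamplingError,
    SMCConfig,
    match_frequencies,
    sample_posterior,
)

__all__ = [
    "EMConfig",
    "EMState",
    "MatchMarginals",
    "beta_prior_from_mean",
    "fit_frechet",
    "initialize_params",
    "expectation",
    "update_phi",
    "update_theta",
    "run_em",
]

logger = logging.getLogger(__name__)

_SHAPE_BOUNDS = (1.0, 200.0)
_SCALE_BOUNDS = (1e-8, 1e12)
_LOG_SCALE_BOUNDS = (math.log(_SCALE_BOUNDS[0]), math.log(_SCALE_BOUNDS[1]))
_PENALTY = 1e15


def _minimize_theta(objective, shape0: float, scale0: float) -> tuple[float, float, float]:
    """Bounded minimization over (shape, log scale), non-finite-safe.

    Returns (shape, scale, objective value); extreme trial points during
    line searches can overflow the Fréchet density, so non-finite
    objective values are replaced by a large penalty.
    """

    def safe(x: np.ndarray) -> float:
        val = objective(float(x[0]), float(math.exp(x[1])))
        return val if math.isfinite(val) else _PENALTY

    x0 = np.array([shape0, math.log(scale0)])
    res = optimize.minimize(
        safe, x0=x0, method="L-BFGS-B",
        bounds=[_SHAPE_BOUNDS, _LOG_SCALE_BOUNDS],
    )
    shape = float(np.clip(res.x[0], *_SHAPE_BOUNDS))
    scale = float(math.exp(np.clip(res.x[1], *_LOG_SCALE_BOUNDS)))
    return shape, scale, float(res.fun)


@dataclass(frozen=True)
class EMConfig:
    """EM loop settings (tolerance is max relative parameter change)."""

    tol: float = 1e-2
    max_iter: int = 30
    init_min_distance: float = 3.0
    candidate_prob_ratio: float = 20.0
    smc: SMCConfig = field(default_factory=SMCConfig)


@dataclass
class EMState:
    """Fitted parameters plus the iteration trace."""

    params: ModelParams
    iteration: int
    param_history: list[dict[str, float]]
    converged: bool


@dataclass(frozen=True)
class MatchMarginals:
    """Posterior marginals: p_match is R×(T+1) (last column NO_MATCH), p_csp R×T."""

    p_match: np.ndarray
    p_csp: np.ndarray

    @property
    def n_ref(self) -> int:
        return self.p_match.shape[0]

    @property
    def n_tgt(self) -> int:
        return self.p_match.shape[1] - 1


def beta_prior_from_mean(mean: float, variance_scale: float = 1.0) -> tuple[float, float]:
    """Beta prior with the given mean and sd = 2 * mean * variance_scale.

    When the moment equations give a pseudo-count below 1 (or an
    infeasible variance), both counts are rescaled by a common factor —
    which leaves the mean invariant — so that min(a, b) == 1.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must be in (0, 1)")
    if variance_scale <= 0:
        raise ValueError("variance_scale must be > 0")
    sd = 2.0 * mean * variance_scale
    var = sd * sd
    nu = mean * (1.0 - mean) / var - 1.0  # a + b
    a, b = mean * nu, (1.0 - mean) * nu
    if nu <= 0 or min(a, b) < 1.0:
        f = 1.0 / min(mean, 1.0 - mean)
        a, b = mean * f, (1.0 - mean) * f
        if min(a, b) < 1.0:  # numerical edge
            a, b = max(a, 1.0), max(b, 1.0)
    return float(a), float(b)


def fit_frechet(
    data: np.ndarray,
    weights: np.ndarray | None = None,
    x0: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Weighted Fréchet MLE with the shape bounded below by 1."""
    data = np.asarray(data, dtype=float)
    data = np.maximum(data, 1e-300)
    if weights is None:
        weights = np.ones_like(data)
    if x0 is None:
        x0 = (1.5, float(np.median(data)))

    def nll(shape: float, scale: float) -> float:
        return -float(np.sum(weights * csp_log_density(data, shape, scale)))

    shape, scale, _ = _minimize_theta(nll, *x0)
    return shape, scale


def initialize_params(
    D: DistanceMatrix,
    expected_csp_fraction: float,
    max_csp_distance: float,
    variance_scale: float = 1.0,
    init_min_distance: float = 3.0,
) -> ModelParams:
    """Initial parameter estimates from row-minimum distances.

    theta0 is a shape-bounded Fréchet MLE over the per-row minimum
    distances after removing values below ``init_min_distance`` (matches
    in the noise regime); if fewer than 3 values survive, a default
    theta0 = (1.5, median of survivors or Dmax/2) is used with a
    warning.  phi0 is the Beta prior mean; omega0 ties the densities at
    ``max_csp_distance``.
    """
    row_min = D.values.min(axis=1) if D.n_tgt else np.empty(0)
    survivors = row_min[row_min >= init_min_distance]
    if survivors.size < 3:
        warnings.warn(
            "fewer than 3 row-minimum distances above the initialization "
            "threshold; falling back to default Frechet start",
            stacklevel=2,
        )
        scale0 = float(np.median(survivors)) if survivors.size else max_csp_distance / 2
        theta0 = (1.5, max(scale0, 1e-8))
    else:
        theta0 = fit_frechet(survivors)
    a, b = beta_prior_from_mean(expected_csp_fraction, variance_scale)
    phi0 = a / (a + b)
    params = ModelParams(
        frechet_shape=theta0[0],
        frechet_scale=theta0[1],
        mixture_weight=phi0,
        nomatch_level=1.0,  # placeholder, replaced by solve_omega below
        prior_a=a,
        prior_b=b,
        max_csp_distance=max_csp_distance,
        dof=D.ndim,
    )
    return params.with_(nomatch_level=solve_omega(params))


def expectation(
    ensemble: Ensemble, D: DistanceMatrix, params: ModelParams
) -> MatchMarginals:
    """Marginal match frequencies and CSP responsibilities.

    ``p_match[r, t]`` is the frequency of the assignment r→t across the
    sampled matchings (uniform weights after resampling); ``p_csp[r, t]``
    is the probability the pair's displacement is a CSP given it matches:
    phi * frechet / (phi * frechet + (1 - phi) * chi2).
    """
    p_match = match_frequencies(ensemble.decisions, D.n_tgt)
    phi = params.mixture_weight
    if phi == 0.0:
        p_csp = np.zeros_like(D.values)
    else:
        log_num = np.log(phi) + csp_log_density(
            D.values, params.frechet_shape, params.frechet_scale
        )
        log_den = match_log_density(D.values, params)
        p_csp = np.exp(np.clip(log_num - log_den, -745, 0))
    return MatchMarginals(p_match=p_match, p_csp=p_csp)


def update_phi(
    marginals: MatchMarginals,
    prior_a: float,
    prior_b: float,
    previous_phi: float,
) -> float:
    """Conjugate Beta MAP update of the mixture weight.

    phi = (sum p_csp * p_match + a - 1) / (sum p_match + a + b - 2) with
    sums over reference–target cells only (NO_MATCH excluded); when no
    matches were sampled the previous value is retained.
    """
    pm = marginals.p_match[:, :-1]
    den = float(pm.sum()) + prior_a + prior_b - 2.0
    if pm.sum() <= 0 or den <= 0:
        warnings.warn("no sampled matches; keeping previous phi", stacklevel=2)
        return previous_phi
    num = float(np.sum(marginals.p_csp * pm)) + prior_a - 1.0
    return float(np.clip(num / den, 0.0, 1.0))


def update_theta(
    marginals: MatchMarginals, D: DistanceMatrix, params: ModelParams
) -> tuple[float, float]:
    """Maximize the expected matched log density over (shape, scale).

    Only matched cells depend on theta, so the sample-averaged objective
    is the p_match-weighted sum of the matched mixture log density; the
    optimizer is warm-started at the current theta, and the previous
    value is kept if it scores at least as well (monotone improvement).
    """
    pm = marginals.p_match[:, :-1]
    mask = pm > 0
    if not np.any(mask) or params.mixture_weight == 0.0:
        return params.frechet_shape, params.frechet_scale
    d = D.values[mask]
    w = pm[mask]

    def neg(shape: float, scale: float) -> float:
        trial = params.with_(frechet_shape=shape, frechet_scale=scale)
        return -float(np.sum(w * match_log_density(d, trial)))

    shape, scale, fval = _minimize_theta(
        neg, params.frechet_shape, params.frechet_scale
    )
    f0 = neg(params.frechet_shape, params.frechet_scale)
    if fval > f0 + 1e-12:
        warnings.warn("theta update did not improve; keeping previous", stacklevel=2)
        return params.frechet_shape, params.frechet_scale
    return shape, scale


def _rel_change(new: float, old: float) -> float:
    return abs(new - old) / max(abs(old), 1e-6)


def run_em(
    ref: PeakList,
    tgt: PeakList,
    expected_csp_fraction: float,
    max_csp_distance: float,
    variance_scale: float = 1.0,
    config: EMConfig = EMConfig(),
    seed: int = 0,
) -> tuple[EMState, MatchMarginals, Ensemble]:
    """Full EM loop: returns fitted state, final marginals, final ensemble.

    Each iteration rebuilds candidate sets and the decision order at the
    current parameters (omega and theta move the filters), samples the
    posterior, and updates phi, theta, omega.  Convergence is a maximum
    relative change below ``config.tol`` across (shape, scale, phi,
    omega); the final marginals come from one extra sampling pass at the
    converged parameters.
    """
    D = compute_distance_matrix(ref, tgt)
    params = initialize_params(
        D,
        expected_csp_fraction,
        max_csp_distance,
        variance_scale,
        config.init_min_distance,
    )
    ss = np.random.SeedSequence(seed)
    history: list[dict[str, float]] = []
    converged = False
    iteration = 0
    last_good: tuple[ModelParams, MatchMarginals, Ensemble] | None = None
    for iteration in range(1, config.max_iter + 1):
        sets, ordering = build_ordering(D, params, config.candidate_prob_ratio)
        try:
            ensemble = sample_posterior(
                D, params, ordering, sets, config.smc, seed=ss.spawn(1)[0]
            )
        except SamplingError:
            if last_good is None:
                raise
            # the current parameters defeat the proposal machinery; stop
            # refining and fall back to the last iterate that sampled
            warnings.warn(
                "sampling failed at the current parameters; "
                "returning the last successful EM iterate", stacklevel=2,
            )
            params, marg, ensemble = last_good
            state = EMState(
                params=params, iteration=iteration,
                param_history=history, converged=False,
            )
            return state, marg, ensemble
        marg = expectation(ensemble, D, params)
        last_good = (params, marg, ensemble)
        phi = update_phi(marg, params.prior_a, params.prior_b, params.mixture_weight)
        trial = params.with_(mixture_weight=phi)
        shape, scale = update_theta(marg, D, trial)
        trial = trial.with_(frechet_shape=shape, frechet_scale=scale)
        try:
            omega = solve_omega(trial)
        except ValueError:
            # the new theta starves the matched density at Dmax; treat as a
            # failed update and keep the previous theta
            warnings.warn(
                "theta update makes the matched density underflow at Dmax; "
                "keeping previous theta", stacklevel=2,
            )
            trial = trial.with_(
                frechet_shape=params.frechet_shape,
                frechet_scale=params.frechet_scale,
            )
            omega = solve_omega(trial)
        new = trial.with_(nomatch_level=omega)
        delta = max(
            _rel_change(new.frechet_shape, params.frechet_shape),
            _rel_change(new.frechet_scale, params.frechet_scale),
            _rel_change(new.mixture_weight, params.mixture_weight),
            _rel_change(new.nomatch_level, params.nomatch_level),
        )
        history.append(
            {
                "iteration": iteration,
                "frechet_shape": new.frechet_shape,
                "frechet_scale": new.frechet_scale,
                "phi": new.mixture_weight,
                "omega": new.nomatch_level,
                "max_rel_change": delta,
            }
        )
        logger.info(
            "EM iter %d: shape=%.3f scale=%.3f phi=%.4f omega=%.3g (d=%.3g)",
            iteration, new.frechet_shape, new.frechet_scale,
            new.mixture_weight, new.nomatch_level, delta,
        )
        params = new
        if delta < config.tol:
            converged = True
            break
    # final pass at the converged parameters
    sets, ordering = build_ordering(D, params, config.candidate_prob_ratio)
    try:
        ensemble = sample_posterior(
            D, params, ordering, sets, config.smc, seed=ss.spawn(1)[0]
        )
        marg = expectation(ensemble, D, params)
    except SamplingError:
        if last_good is None:
            raise
        warnings.warn(
            "final sampling pass failed; reusing the last EM iterate's sample",
            stacklevel=2,
        )
        params, marg, ensemble = last_good
        converged = False
    state = EMState(
        params=params, iteration=iteration, param_history=history, converged=converged
    )
    if not converged:
        warnings.warn("EM reached max_iter without converging", stacklevel=2)
    return state, marg, ensemble
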