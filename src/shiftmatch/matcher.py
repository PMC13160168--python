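"""High-level estimator interface.

:class:`PeakMatcher` wraps the whole pipeline — distance features,
candidate ordering, SMC posterior sampling, EM parameter fitting,
report assembly — behind a scikit-learn-style estimator: configure in
``__init__``, call :meth:`fit` with a reference and a target peak list,
read fitted attributes (trailing underscore), then :meth:`predict` the
best decision per reference peak or pull full reports.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import analysis
from .em import EMConfig, EMState, MatchMarginals, run_em
from .model import compute_distance_matrix, max_csp_to_distance
from .peaklist import NO_MATCH, PeakList, validate_pair
from .smc import Ensemble, SMCConfig

__all__ = ["PeakMatcher", "match_peaks"]


class PeakMatcher(BaseEstimator):
    """Probabilistic cross-peak matcher between two NMR peak lists.

    Parameters
    ----------
    expected_csp_fraction:
        Rough prior fraction of reference peaks expected to carry a CSP;
        sets the mean of the Beta prior on the mixture weight.
    max_csp_ppm:
        Largest combined CSP (ppm) the user expects; fixes where the
        matched and non-matched densities cross.  Ignored when
        ``max_csp_distance`` is given directly (normalized squared
        distance units).
    variance_scale:
        Multiplier on the Beta prior's default SD (2x its mean).
    candidate_prob_ratio:
        Candidate/overlap probability-ratio filter (default 20).
    csp_cutoff_ppm, mass_cutoff:
        CSP significance cutoff and marginal-mass confidence cutoff for
        detection.
    em_tol, em_max_iter, min_particles, beam_width, beam_width_cap,
    ess_threshold, freq_tolerance, max_doublings:
        EM and SMC controls; see :class:`shiftmatch.em.EMConfig` and
        :class:`shiftmatch.smc.SMCConfig`.
    seed:
        Integer seed for all sampling randomness.

    Attributes
    ----------
    params_ : ModelParams
        Converged likelihood-model parameters.
    em_state_ : EMState
        Iteration trace and convergence flag.
    marginals_ : MatchMarginals
        Posterior marginals (R x (T+1) match frequencies, CSP
        responsibilities).
    p_match_ : ndarray
        Alias of ``marginals_.p_match``.
    ensemble_ : Ensemble
        Final posterior sample of complete matchings.
    """

    def __init__(
        self,
        expected_csp_fraction: float = 0.1,
        max_csp_ppm: float = 0.2,
        max_csp_distance: float | None = None,
        variance_scale: float = 2.0,
        candidate_prob_ratio: float = 20.0,
        csp_cutoff_ppm: float = 0.01,
        mass_cutoff: float = 0.95,
        em_tol: float = 1e-2,
        em_max_iter: int = 30,
        init_min_distance: float = 3.0,
        min_particles: int = 64,
        beam_width: int = 1000,
        beam_width_cap: int = 25_000,
        ess_threshold: float = 0.2,
        freq_tolerance: float = 0.1,
        max_doublings: int = 8,
        seed: int = 0,
    ):
        self.expected_csp_fraction = expected_csp_fraction
        self.max_csp_ppm = max_csp_ppm
        self.max_csp_distance = max_csp_distance
        self.variance_scale = variance_scale
        self.candidate_prob_ratio = candidate_prob_ratio
        self.csp_cutoff_ppm = csp_cutoff_ppm
        self.mass_cutoff = mass_cutoff
        self.em_tol = em_tol
        self.em_max_iter = em_max_iter
        self.init_min_distance = init_min_distance
        self.min_particles = min_particles
        self.beam_width = beam_width
        self.beam_width_cap = beam_width_cap
        self.ess_threshold = ess_threshold
        self.freq_tolerance = freq_tolerance
        self.max_doublings = max_doublings
        self.seed = seed

    def _em_config(self) -> EMConfig:
        return EMConfig(
            tol=self.em_tol,
            max_iter=self.em_max_iter,
            init_min_distance=self.init_min_distance,
            candidate_prob_ratio=self.candidate_prob_ratio,
            smc=SMCConfig(
                min_particles=self.min_particles,
                beam_width=self.beam_width,
                beam_width_cap=self.beam_width_cap,
                ess_threshold=self.ess_threshold,
                freq_tolerance=self.freq_tolerance,
                max_doublings=self.max_doublings,
            ),
        )

    def fit(self, ref: PeakList, tgt: PeakList) -> "PeakMatcher":
        """Fit the model by EM and sample the final matching posterior."""
        validate_pair(ref, tgt)
        if self.max_csp_distance is not None:
            dmax = float(self.max_csp_distance)
        else:
            scales = analysis.resolve_scales(ref)
            dmax = max_csp_to_distance(self.max_csp_ppm, ref, tgt, scales)
        state, marg, ensemble = run_em(
            ref,
            tgt,
            expected_csp_fraction=self.expected_csp_fraction,
            max_csp_distance=dmax,
            variance_scale=self.variance_scale,
            config=self._em_config(),
            seed=self.seed,
        )
        self.ref_ = ref
        self.tgt_ = tgt
        self.params_ = state.params
        self.em_state_: EMState = state
        self.marginals_: MatchMarginals = marg
        self.p_match_ = marg.p_match
        self.p_csp_ = marg.p_csp
        self.ensemble_: Ensemble = ensemble
        self.n_iter_ = state.iteration
        self.converged_ = state.converged
        self.distance_matrix_ = compute_distance_matrix(ref, tgt)
        return self

    def predict(self) -> np.ndarray:
        """Best decision per reference peak: target index or -1 for NO_MATCH."""
        self._check_fitted()
        best = analysis.best_matches(self.marginals_, self.mass_cutoff)
        return np.array(
            [-1 if b["decision"] == NO_MATCH else b["decision"] for b in best]
        )

    def report(self) -> analysis.MatchReport:
        """Full per-reference match report (best match, CSP mass/estimates)."""
        self._check_fitted()
        return analysis.build_match_report(
            self.marginals_,
            self.ref_,
            self.tgt_,
            cutoff=self.mass_cutoff,
            csp_cutoff_ppm=self.csp_cutoff_ppm,
            mass_cutoff=self.mass_cutoff,
        )

    def csp_detection(self):
        """Marginal-mass CSP detection table (see :func:`analysis.csp_detection`)."""
        self._check_fitted()
        return analysis.csp_detection(
            self.marginals_, self.ref_, self.tgt_,
            csp_cutoff_ppm=self.csp_cutoff_ppm, mass_cutoff=self.mass_cutoff,
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "marginals_"):
            raise RuntimeError("PeakMatcher is not fitted; call fit() first")


def match_peaks(ref: PeakList, tgt: PeakList, **params) -> PeakMatcher:
    """Functional one-call interface: fit a :class:`PeakMatcher` and return it."""
    return PeakMatcher(**params).fit(ref, tgt)
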