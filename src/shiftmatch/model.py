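"""Distance features and the three-component likelihood model.

The matching model classifies every reference–target squared distance
into one of three categories, each with its own density on the
uncertainty-normalized squared distance d:

* matched, displaced only by noise — chi-squared with K degrees of
  freedom (K = number of spectral dimensions), exact under Gaussian
  positional noise with the stated per-dimension uncertainties;
* matched, displaced by a genuine chemical shift perturbation (CSP) —
  Fréchet (inverse Weibull) with shape ``alpha >= 1`` and scale ``s``,
  a heavy-tailed law learned from the data;
* not matched — an improper uniform pseudo-density 1/omega, constant
  in d.

The matched density is the two-component mixture with weight ``phi`` on
the CSP branch.  ``omega`` is pinned by requiring the matched and
non-matched densities to cross exactly at the normalized squared
distance ``Dmax`` corresponding to the largest CSP the user expects.

All arithmetic is carried out in log space; matrix-level likelihoods are
assembled from log-densities downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .peaklist import PeakList, PeakListError, validate_pair

__all__ = [
    "DistanceMatrix",
    "ModelParams",
    "compute_distance_matrix",
    "noise_log_density",
    "csp_log_density",
    "nomatch_log_density",
    "match_log_density",
    "solve_omega",
    "max_csp_to_distance",
    "DEFAULT_NUCLEUS_SCALES",
]

#: Combined-CSP scale factor per nucleus (¹H is the unit axis).
DEFAULT_NUCLEUS_SCALES = {"H": 1.0, "N": 0.101, "C": 0.252}

# chi2 at d == 0 diverges for K == 1; identical quantized coordinates do
# occur, so clamp just above zero.
_D_FLOOR = np.finfo(float).eps * 10


@dataclass(frozen=True)
class DistanceMatrix:
    """R×T matrix of uncertainty-normalized squared distances."""

    values: np.ndarray
    ndim: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("distance matrix must be 2-D")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("distances must be finite and >= 0")
        object.__setattr__(self, "values", v)

    @property
    def n_ref(self) -> int:
        return self.values.shape[0]

    @property
    def n_tgt(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the three-component matching likelihood.

    Attributes
    ----------
    frechet_shape, frechet_scale:
        Fréchet shape ``alpha >= 1`` (dimensionless) and scale ``s > 0``
        (units of normalized squared distance) of the CSP branch.
    mixture_weight:
        ``phi`` in [0, 1], prior probability that a matched pair carries
        a CSP rather than pure noise.
    nomatch_level:
        ``omega > 0``; the non-match pseudo-density is ``1/omega``.
    prior_a, prior_b:
        Beta prior pseudo-counts for ``phi`` (each >= 1); ``prior_a`` is
        the CSP-category count.
    max_csp_distance:
        ``Dmax``, the normalized squared distance of the largest CSP the
        user expects; the point where matched and non-matched densities
        are tied.
    dof:
        K, the number of spectral dimensions (chi-squared dof).
    """

    frechet_shape: float
    frechet_scale: float
    mixture_weight: float
    nomatch_level: float
    prior_a: float
    prior_b: float
    max_csp_distance: float
    dof: int

    def __post_init__(self) -> None:
        if not self.frechet_shape >= 1:
            raise ValueError("frechet_shape must be >= 1")
        if not self.frechet_scale > 0:
            raise ValueError("frechet_scale must be > 0")
        if not 0.0 <= self.mixture_weight <= 1.0:
            raise ValueError("mixture_weight must be in [0, 1]")
        if not self.nomatch_level > 0:
            raise ValueError("nomatch_level must be > 0")
        if self.prior_a < 1 or self.prior_b < 1:
            raise ValueError("Beta prior parameters must be >= 1")
        if not (self.max_csp_distance > 0 and math.isfinite(self.max_csp_distance)):
            raise ValueError("max_csp_distance must be positive and finite")
        if self.dof < 1:
            raise ValueError("dof must be >= 1")

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)


def compute_distance_matrix(ref: PeakList, tgt: PeakList) -> DistanceMatrix:
    """Normalized squared distances between all reference/target pairs.

    ``D[r, t] = sum_k (delta_r_k - delta_t_k)**2 / (sigma_r_k**2 + sigma_t_k**2)``
    """
    validate_pair(ref, tgt)
    dr = ref.shift_array()[:, None, :]  # (R, 1, K)
    dt = tgt.shift_array()[None, :, :]  # (1, T, K)
    pooled = np.asarray(ref.sigmas, float) ** 2 + np.asarray(tgt.sigmas, float) ** 2
    d = np.sum((dr - dt) ** 2 / pooled, axis=2)
    return DistanceMatrix(values=d, ndim=ref.ndim)


def noise_log_density(d, dof: int):
    """Log chi-squared(K) PDF at normalized squared distance d (noise-only match)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    if dof < 1:
        raise ValueError("dof must be >= 1")
    out = stats.chi2.logpdf(np.maximum(d, _D_FLOOR), df=dof)
    return out if out.shape else float(out)


def csp_log_density(d, shape: float, scale: float):
    """Log Fréchet PDF at d (CSP match); 0 density (-inf) at d == 0."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    if not (shape >= 1 and scale > 0):
        raise ValueError("require shape >= 1 and scale > 0")
    with np.errstate(invalid="ignore", over="ignore"):
        out = stats.invweibull.logpdf(d, c=shape, scale=scale)
    out = np.where(d == 0, -np.inf, out)  # analytic limit; scipy yields NaN
    return out if out.shape else float(out)


def nomatch_log_density(params: ModelParams) -> float:
    """Log of the constant non-match pseudo-density, log(1/omega)."""
    return -math.log(params.nomatch_level)


def match_log_density(d, params: ModelParams):
    """Log matched-pair density: mixture of CSP (weight phi) and noise branches."""
    d = np.asarray(d, dtype=float)
    phi = params.mixture_weight
    log_noise = noise_log_density(d, params.dof)
    if phi == 0.0:
        out = np.asarray(log_noise)
        return out if out.shape else float(out)
    log_csp = csp_log_density(d, params.frechet_shape, params.frechet_scale)
    if phi == 1.0:
        out = np.asarray(log_csp)
        return out if out.shape else float(out)
    with np.errstate(invalid="ignore"):
        out = np.logaddexp(math.log(phi) + log_csp, math.log1p(-phi) + log_noise)
    out = np.where(np.isnan(out), -np.inf, out)  # both branches underflowed
    return out if out.shape else float(out)


def solve_omega(params: ModelParams) -> float:
    """omega making matched and non-matched densities equal at Dmax.

    Returns ``1 / match_density(Dmax)``; afterwards
    ``match_log_density(Dmax) == -log(omega)`` exactly.  When the matched
    density at Dmax is positive but below exp(-700) — e.g. a pure-noise
    mixture (phi = 0) with a very large Dmax — omega is clamped at the
    largest representable value, which moves the effective crossing point
    inward; a density of exactly zero raises.
    """
    log_m = match_log_density(params.max_csp_distance, params)
    if not np.isfinite(log_m):
        raise ValueError(
            "matched density is zero at max_csp_distance; "
            "use a smaller expected maximum CSP"
        )
    return float(math.exp(min(-log_m, 700.0)))


def max_csp_to_distance(
    max_csp_ppm: float,
    ref: PeakList,
    tgt: PeakList,
    scales: Sequence[float],
) -> float:
    """Convert the largest expected combined CSP (ppm) to a normalized squared distance.

    CSP magnitudes are combined values (heteronuclear dimensions scaled
    before the Euclidean distance), so the largest expected CSP bounds
    the combined displacement.  It is laid out with every dimension
    contributing equally: a shift of ``max_csp_ppm / (sqrt(K) * scale_k)``
    along each dimension, whose combined CSP is exactly ``max_csp_ppm``,
    then normalized by the pooled variances exactly as the distance
    matrix is.
    """
    if max_csp_ppm <= 0:
        raise ValueError("max CSP must be > 0")
    if len(scales) != ref.ndim:
        raise PeakListError("scales length must equal dimensionality")
    pooled = np.asarray(ref.sigmas, float) ** 2 + np.asarray(tgt.sigmas, float) ** 2
    per_dim = max_csp_ppm / math.sqrt(ref.ndim)
    disp = np.array([per_dim / s for s in scales])
    return float(np.sum(disp ** 2 / pooled))
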