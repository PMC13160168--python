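# Methods

## Model

A matching between R reference and T target cross-peaks is a binary
R×T matrix **M** with at most one 1 per row and per column; all-zero
rows and columns encode unmatched peaks (vanished, or never picked).
Writing D_rt for the uncertainty-normalized squared distance

    D_rt = Σ_k (δ_r,k − δ_t,k)² / (σ_r,k² + σ_t,k²),

the likelihood of a matrix classifies every cell into one of three
categories:

* **M_rt = 1, noise only.** The two peak positions are modelled as
  Gaussians centred on the observed shifts with the stated per-dimension
  uncertainties, which makes D_rt exactly χ²-distributed with K degrees
  of freedom (K = spectral dimensionality).
* **M_rt = 1, CSP.** Genuinely perturbed matches are modelled as
  Fréchet (inverse-Weibull) random variables on D_rt with shape α ≥ 1
  and scale s — a heavy tail that tolerates large movements.
* **M_rt = 0.** Distances between unrelated peaks are approximately
  uniform over the scale of interest, giving a constant pseudo-density
  1/ω.

The matched-pair density is the two-component mixture with weight φ on
the CSP branch. The full-matrix likelihood is the product of cell
densities, and the posterior over matchings is this likelihood
normalized over all valid matrices (uniform prior). A per-cell latent
indicator C_rt (CSP vs noise, independent across cells given the
matching) carries the second classification level.

ω is not free: given a user statement of the largest combined CSP they
expect, it is set so that the matched and non-matched densities are
equal at the corresponding normalized squared distance Dmax
(`solve_omega`). Beyond that distance the model prefers "the original
peak disappeared and an unrelated peak appeared" to "the peak moved".

### Converting the largest expected CSP to Dmax

Combined CSPs weight heteronuclear dimensions before the Euclidean
norm (scale factors 1 for ¹H, 0.101 for ¹⁵N, 0.252 for ¹³C). The
user's `max_csp_ppm` is interpreted as a *combined* magnitude: it is
laid out as a displacement of `max_csp_ppm/√K` of combined CSP per
dimension (i.e. `max_csp_ppm/(√K·scale_k)` ppm along axis k), whose
combined CSP is exactly `max_csp_ppm`, and normalized by the pooled
variances like any other distance. Users who prefer full control can
set `max_csp_distance` directly in normalized squared distance units.

When the matched density at Dmax is positive but smaller than exp(−700)
(e.g. φ = 0 with a very large Dmax), ω is clamped at the largest
representable value; this moves the effective crossing inward but keeps
the run numerically well-defined. A matched density of exactly zero at
Dmax raises an error suggesting a smaller maximum CSP.

## Sampling the posterior

Exact normalization over all matchings is combinatorially intractable,
so matrices are sampled by sequential Monte Carlo over per-row
decisions (target index or NO_MATCH). The row-decision likelihood
matrix S has S_rt = (matched density at D_rt) × (1/ω)^(T−1) and
S_r,NO_MATCH = (1/ω)^T; a complete decision vector's product of S
entries equals the matrix likelihood.

**Candidate sets and decision order.** For each reference peak, targets
whose matched density falls below 1/ω are eliminated; survivors plus
the no-match pseudo-candidate are normalized to probabilities and
targets below 1/20 of the best target's probability are dropped
(`candidate_prob_ratio`, default 20). References sharing candidates
whose probabilities lie within a factor of 20 are connected by edges of
length 1/overlap-count; Floyd–Warshall shortest paths feed
single-linkage clustering cut at height 1.0 — exactly the connected
components of the finite-distance graph, since hop lengths never exceed
1 — and optimal leaf ordering of the dendrogram yields a decision order
in which competing peaks are adjacent and clusters are contiguous.

**Beam-search proposal.** Each particle draws the current row's
decision from a lookahead proposal: the weight of decision a is
S_row,a times a beam-search estimate (width 1000 by default) of the
partition function over the remaining rows of the cluster, respecting
targets consumed by the particle and along each beam. Particles with
identical consumed-target patterns over the cluster's candidate pool
share one proposal computation, and partition-function completions are
memoized within a cluster pass.

**Resampling and adaptation.** After the last row of each cluster the
ensemble's effective-sample-size ratio (Σw)²/(N·Σw²) is computed. At or
above 0.2 the ensemble is stratified-resampled and sampling proceeds;
below 0.2 the cluster's decisions are discarded and the beam width is
multiplied by 5. Two special cases refine this rule:

* if the beam never truncated, the lookahead was already exhaustive and
  a wider beam cannot change the proposal — the low ESS then reflects
  competition for a target shared with an *earlier* cluster (possible
  because the factor-20 overlap rule is a heuristic), and the sampler
  resamples anyway rather than escalating fruitlessly;
* if the width would exceed `beam_width_cap` (default 25,000) the run
  aborts with a proposal-failure error. The default cap is deliberately
  modest: by the time a wider retry could complete, the cost of a
  single cluster pass is prohibitive, so failing fast is more useful
  than failing after hours.

The particle count starts at max(R, 64). After a full pass a second
independent ensemble is drawn; if any reference–target marginal
frequency differs by more than 0.1 between the two, N doubles (up to 8
doublings) and sampling repeats. When the check passes the ensembles
are merged, so the returned sample has at least 2·max(R, 64) uniform-
weight particles.

## Fitting θ, φ, ω by EM

* **Initialization.** The smallest distance in each row, with values
  below `init_min_distance` (default 3) removed, feeds a shape-bounded
  (α ≥ 1) Fréchet maximum-likelihood fit for θ₀; fewer than 3 survivors
  triggers a default start (shape 1.5, scale = median survivor or
  Dmax/2) with a warning. The Beta prior on φ has mean equal to the
  user's expected CSP fraction and standard deviation 2·mean·
  `variance_scale`; if the moment equations give a pseudo-count below 1
  (or an infeasible variance), both counts are rescaled by a common
  factor — preserving the mean — until min(a, b) = 1. φ₀ is the prior
  mean; ω₀ comes from the crossing condition.
* **E step.** The sampler runs at the current parameters; marginal
  match frequencies p_match (including the NO_MATCH column) are the
  per-pair frequencies over the uniform-weight ensemble, and CSP
  responsibilities are p_csp = φ·Fréchet/(φ·Fréchet + (1−φ)·χ²).
* **M step.** φ gets the conjugate Beta MAP update
  (Σ p_csp·p_match + a − 1)/(Σ p_match + a + b − 2) over target cells,
  clamped to [0,1] and left unchanged (with a warning) when no matches
  were sampled. θ maximizes the p_match-weighted matched log density
  numerically (L-BFGS-B over shape and log-scale, warm-started,
  non-finite objective values replaced by a penalty); if the optimum
  does not improve on the previous iterate, or makes the matched
  density underflow at Dmax, the previous θ is kept with a warning.
  ω is recomputed from the crossing condition.
* **Convergence.** Maximum relative change across (α, s, φ, ω) below
  `em_tol` (default 1e-2), or `em_max_iter` (default 30) iterations.
  A final sampling pass at the converged parameters produces the
  reported marginals. If a sampling pass fails outright after at least
  one successful iteration, the last successful iterate is returned
  flagged non-converged rather than aborting the analysis.

## Reports and evaluation

Per reference peak the report carries the highest-probability decision
(ties broken toward the lower target index and flagged), its marginal
probability, the combined CSP of the best match, the marginal
probability mass on targets whose combined CSP exceeds the significance
cutoff (default 0.01 ppm; detection at mass ≥ 0.95), and a
probability-weighted mean and population SD of the combined CSP over
target matches. Mass-based detection deliberately tolerates ambiguity:
a reference whose mass is split among several significantly perturbed
targets is still a confident hit even though no single match is.

Against ground truth, accuracy is the fraction of made matches that are
correct and completeness the fraction of true matches recovered, both
swept over posterior-probability cutoffs; per-bin accuracies are
reported with empty bins left undefined. Found/missed histograms bin
true matches by CSP magnitude, "found" meaning correct with posterior
at or above 0.95.

## Synthetic data

The generator (`shiftmatch.synthetic`) draws reference peaks uniformly
over a ppm window with a Poisson-disk minimum spacing measured in
pooled-uncertainty units. Matched targets are the reference positions
plus per-dimension Gaussian jitter with SD equal to the pooled
uncertainty, making noise-only matched distances exactly χ²_K. A chosen
fraction of matched peaks instead receive a displacement whose
normalized squared distance is drawn from the configured Fréchet law in
a uniformly random direction — data generated exactly from the matched
mixture, the regime in which parameter recovery is well-posed. A
fraction of reference peaks is dropped from the target list and
spurious targets are added uniformly.

The default benchmark emulates a ¹H–¹⁵N amide spectrum pair from a
fragment-screening setting: 200 peaks over 6.5–10 × 100–135 ppm,
uncertainties 0.0015/0.015 ppm, CSP fraction 0.1, Fréchet(1.5, 8), 5%
drops and 5% spurious peaks. The crowded preset packs 120 peaks into a
0.2 × 2.0 ppm window (minimum spacing 3 pooled-σ) with CSP fraction
0.3, so roughly a third to a half of reference peaks compete for two or
more candidate targets. The window density is chosen below the
percolation threshold of the candidate-overlap graph: in denser windows
competition chains into clusters spanning dozens of peaks, where beam
truncation degrades the proposal, widths escalate and runtime becomes
heavy-tailed — the method's own documented failure regime.

**What the synthetic benchmark does not show.** Real peak lists have
correlated pick errors, intensity-dependent position uncertainty,
lineshape overlap and systematic referencing offsets, none of which the
generator emulates; CSP directions in real titrations are also not
isotropic. Passing benchmarks therefore demonstrate correctness of the
inference machinery under the model's own assumptions, not performance
on any particular spectrometer output.

## Problem sizes used in tests

The test suite and the acceptance script use 10 benchmark instances
(R = 200) for parameter recovery and calibration, 20 small instances
(R, T ≤ 4) against the exact enumeration oracle, and 3 crowded
instances (R = 120) for the detection comparison — sizes at which a
full run of everything completes in a few minutes on one core.
Instance seeds are fixed (they define the study conditions); sampler
seeds derive from the run seed.

## Known limitations

* The Fréchet shape is estimated with a downward bias at the benchmark
  conditions (median ≈ 1.1 against a generating 1.5): dropped reference
  peaks occasionally capture free far-away targets inside the Dmax
  shell, and those few large-distance cells drag the tail fit. The
  scale and the mixture weight are recovered accurately.
* The non-match density is improper (uniform), so ω depends entirely on
  the user's maximum-CSP statement; an overly generous Dmax inflates
  far-match artifacts, an overly tight one suppresses genuine large
  CSPs.
* Candidate filtering truncates the sampled support: decisions whose
  matched density falls below the no-match level (or far below the
  row's best candidate) cannot be sampled. On well-separated data the
  truncated posterior mass is negligible (measured ≤ 4e-4 total
  variation on benchmark-like instances), but in pathological geometry
  it can be material; the truncation is also what keeps repeated
  per-cluster resampling from depleting the ensemble, so it is a
  structural part of the algorithm, not an optimization.
* Exchange regimes beyond fast exchange (peak doubling, intermediate
  broadening) are only represented as dropped/spurious peaks.
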