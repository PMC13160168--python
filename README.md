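# shiftmatch

Probabilistic matching of cross-peaks between two multidimensional NMR
peak lists, with calibrated posterior probabilities for every proposed
match.

## The problem

Comparing two related NMR spectra — a reference and a perturbed target
(ligand added, temperature or pH changed, a different triple-resonance
experiment) — requires mapping each reference cross-peak to its
counterpart in the target list. Done by hand this is slow and, in
crowded spectral regions, ambiguous: several target peaks can plausibly
continue one reference peak, peaks vanish (exchange broadening, missed
picks) and spurious peaks appear. `shiftmatch` treats the entire
matching matrix **M** (an R×T binary matrix with at most one 1 per row
and column; all-zero rows/columns mean "no match") as a random variable
and samples its Bayesian posterior, so every reference→target
assignment — including "no match" — comes with a probability that can
be trusted as a confidence score.

## The model

For reference peak r and target peak t with chemical shifts δ (ppm) and
per-dimension positional uncertainties σ (ppm), the feature is the
uncertainty-normalized squared distance

    D_rt = Σ_k (δ_r,k − δ_t,k)² / (σ_r,k² + σ_t,k²)

Each D_rt falls in one of three classes, each with its own density:

* **matched, noise only** — χ² with K degrees of freedom (K = number of
  spectral dimensions); exact under Gaussian positional noise;
* **matched, genuine chemical shift perturbation (CSP)** — Fréchet
  (shape α ≥ 1, scale s), a heavy-tailed law fit to the data;
* **not matched** — a constant pseudo-density 1/ω.

The matched density is the mixture φ·Fréchet + (1−φ)·χ²; ω is pinned so
the matched and non-matched densities cross exactly at the normalized
distance of the largest CSP the user expects. Posterior sampling uses a
sequential Monte Carlo sampler: reference peaks are ordered so that
peaks competing for the same targets are decided consecutively
(candidate filtering, overlap graph, Floyd–Warshall, single-linkage
clustering, optimal leaf ordering); each decision is drawn from a
beam-search lookahead proposal; ensembles are stratified-resampled per
cluster with ESS-gated beam widening, and the particle count grows
until marginal frequencies stabilize. The unknown parameters (α, s, φ,
ω) are fit by expectation–maximization with a Beta prior on φ.

## Worked example

```python
import numpy as np
from shiftmatch import PeakMatcher, generate_pair, benchmark_config

# a synthetic ¹H-¹⁵N amide pair: 200 reference peaks, 10% carrying CSPs,
# 5% of peaks dropped from the target and 5% spurious peaks added
ref, tgt, truth = generate_pair(benchmark_config(seed=2))

matcher = PeakMatcher(
    expected_csp_fraction=0.1,  # prior fraction of perturbed peaks
    max_csp_ppm=0.2,            # largest combined CSP expected
    variance_scale=2.0,
    seed=5,
).fit(ref, tgt)

p = matcher.params_
print(f"converged={matcher.converged_} after {matcher.n_iter_} iterations")
print(f"Frechet shape={p.frechet_shape:.2f} scale={p.frechet_scale:.2f} "
      f"phi={p.mixture_weight:.3f}")

pred = matcher.predict()          # best target per reference (-1 = no match)
tm = truth.true_matching
best_prob = matcher.p_match_[np.arange(len(ref)),
                             np.where(pred >= 0, pred, matcher.marginals_.n_tgt)]
confident = (pred >= 0) & (best_prob >= 0.95)
print(f"accuracy at 0.95 cutoff: {np.mean(pred[confident] == tm[confident]):.3f}")
print(f"completeness: {np.sum((pred == tm) & confident) / np.sum(tm >= 0):.3f}")
```

Output:

```
converged=True after 4 iterations
Frechet shape=2.86 scale=9.46 phi=0.087
accuracy at 0.95 cutoff: 1.000
completeness: 1.000
```

The fitted mixture weight (0.087) estimates the true CSP fraction
(0.10); every confident match is correct, and all true matches are
recovered at the 0.95 cutoff. `matcher.report()` returns the full
per-reference table (best match, posterior, combined CSP,
marginal-mass CSP detection, probability-weighted CSP estimate), and
`shiftmatch.peaklist.write_match_report` writes it as CSV.

The same pipeline is available from the shell:

```bash
shiftmatch simulate --n-ref 200 --seed 1 --out-prefix demo
shiftmatch match --reference demo_reference.csv --target demo_target.csv \
    --sigmas-ref 0.0015,0.015 --sigmas-tgt 0.0015,0.015 \
    --max-csp 0.2 --csp-fraction 0.1 --variance-scale 2 --seed 7 --out m.csv
shiftmatch evaluate --report m.csv --truth demo_truth.csv --out eval.csv
```

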