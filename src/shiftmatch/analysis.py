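"""Reports, CSP detection, and accuracy/completeness evaluation.

Downstream of the posterior marginals, three questions matter to a
spectroscopist: which target (if any) does each reference peak match,
and how confidently; has the peak undergone a significant chemical
shift perturbation (CSP), regardless of exactly which target it moved
to; and — when ground truth is available — how accurate and complete
the proposed matches are as a function of the posterior cutoff.

Combined CSPs weight heteronuclear dimensions by the usual amide
convention (N x 0.101, C x 0.252, H unscaled) before the Euclidean
distance.  CSP detection sums the marginal mass over all targets whose
combined CSP exceeds the significance cutoff (default 0.01 ppm) and
flags the reference when that mass reaches the confidence cutoff
(default 0.95) — tolerant of ambiguity about *which* perturbed target
is the true match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .em import MatchMarginals
from .peaklist import NO_MATCH, Peak, PeakList, PeakListError
from .model import DEFAULT_NUCLEUS_SCALES

__all__ = [
    "MatchReportRow",
    "MatchReport",
    "EvaluationResult",
    "resolve_scales",
    "combined_csp",
    "csp_matrix",
    "best_matches",
    "evaluate_decisions",
    "csp_detection",
    "csp_estimate",
    "build_match_report",
    "evaluate",
]


@dataclass(frozen=True)
class MatchReportRow:
    reference_id: int
    reference_label: str
    target_id: object  # int or the literal NO_MATCH string
    target_label: str
    posterior_probability: float
    csp_ppm: float | None
    csp_posterior_mass: float
    csp_estimate_mean: float | None
    csp_estimate_sd: float | None
    tie: bool = False


@dataclass(frozen=True)
class MatchReport:
    rows: list[MatchReportRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])


@dataclass(frozen=True)
class EvaluationResult:
    """Binned accuracy/completeness table plus found/missed CSP histograms."""

    bins: pd.DataFrame          # bin_low, bin_high, n, accuracy, cum_accuracy, cum_completeness
    csp_found: np.ndarray       # counts per CSP bin, detected true matches
    csp_missed: np.ndarray      # counts per CSP bin, missed true matches
    csp_bin_edges: np.ndarray


def resolve_scales(
    peaklist: PeakList, scales: "dict[str, float] | None" = None
) -> np.ndarray:
    """Per-dimension combined-CSP scale factors from the axis nuclei."""
    table = dict(DEFAULT_NUCLEUS_SCALES)
    if scales:
        table.update(scales)
    if peaklist.axis_nuclei is None:
        raise PeakListError(
            "peak list has no axis_nuclei; supply explicit scale factors"
        )
    out = []
    for nuc in peaklist.axis_nuclei:
        key = nuc.strip().upper().lstrip("0123456789")
        if key not in table:
            raise PeakListError(f"no combined-CSP scale factor for nucleus {nuc!r}")
        out.append(table[key])
    return np.asarray(out, dtype=float)


def combined_csp(ref_peak: Peak, tgt_peak: Peak, scales) -> float:
    """Combined CSP in ppm: Euclidean distance after per-dimension scaling."""
    a = np.asarray(ref_peak.shifts, float)
    b = np.asarray(tgt_peak.shifts, float)
    s = np.asarray(scales, float)
    if a.shape != b.shape or a.shape != s.shape:
        raise PeakListError("dimension mismatch in combined_csp")
    return float(np.sqrt(np.sum((s * (a - b)) ** 2)))


def csp_matrix(ref: PeakList, tgt: PeakList, scales) -> np.ndarray:
    """(R, T) matrix of combined CSPs between all peak pairs."""
    a = ref.shift_array()[:, None, :]
    b = tgt.shift_array()[None, :, :]
    s = np.asarray(scales, float)
    return np.sqrt(np.sum((s * (a - b)) ** 2, axis=2))


def best_matches(marginals: MatchMarginals, cutoff: float = 0.95) -> list[dict]:
    """Highest-marginal-probability decision per reference peak.

    Ties go to the lowest target index and are flagged; rows whose best
    probability falls below ``cutoff`` are flagged (``below_cutoff``)
    rather than removed.
    """
    out = []
    T = marginals.n_tgt
    for r in range(marginals.n_ref):
        row = marginals.p_match[r]
        best = int(np.argmax(row))  # argmax takes the first (lowest) index on ties
        tie = bool(np.sum(np.isclose(row, row[best], rtol=0, atol=1e-12)) > 1)
        out.append(
            {
                "reference_id": r,
                "decision": NO_MATCH if best == T else best,
                "probability": float(row[best]),
                "tie": tie,
                "below_cutoff": bool(row[best] < cutoff),
            }
        )
    return out


def csp_detection(
    marginals: MatchMarginals,
    ref: PeakList,
    tgt: PeakList,
    csp_cutoff_ppm: float = 0.01,
    mass_cutoff: float = 0.95,
    scales=None,
) -> pd.DataFrame:
    """Marginal-mass CSP detection per reference peak.

    ``csp_posterior_mass`` sums the match marginals over targets whose
    combined CSP exceeds ``csp_cutoff_ppm`` (NO_MATCH mass never
    counts); ``detected`` is mass >= ``mass_cutoff``.
    """
    if scales is None:
        scales = resolve_scales(ref)
    csp = csp_matrix(ref, tgt, scales)
    significant = csp > csp_cutoff_ppm
    mass = np.sum(marginals.p_match[:, :-1] * significant, axis=1)
    return pd.DataFrame(
        {
            "reference_id": np.arange(marginals.n_ref),
            "csp_posterior_mass": mass,
            "detected": mass >= mass_cutoff,
        }
    )


def csp_estimate(
    marginals: MatchMarginals, ref: PeakList, tgt: PeakList, scales=None
) -> pd.DataFrame:
    """Probability-weighted CSP magnitude (mean, population SD) per reference.

    Weights are the match marginals renormalized over target (non-
    NO_MATCH) mass; rows with zero target mass get NaN estimates.
    """
    if scales is None:
        scales = resolve_scales(ref)
    csp = csp_matrix(ref, tgt, scales)
    pm = marginals.p_match[:, :-1]
    total = pm.sum(axis=1)
    mean = np.full(marginals.n_ref, np.nan)
    sd = np.full(marginals.n_ref, np.nan)
    ok = total > 0
    w = pm[ok] / total[ok, None]
    mean[ok] = np.sum(w * csp[ok], axis=1)
    sd[ok] = np.sqrt(np.maximum(np.sum(w * (csp[ok] - mean[ok, None]) ** 2, axis=1), 0.0))
    return pd.DataFrame(
        {"reference_id": np.arange(marginals.n_ref), "csp_mean": mean, "csp_sd": sd}
    )


def build_match_report(
    marginals: MatchMarginals,
    ref: PeakList,
    tgt: PeakList,
    cutoff: float = 0.95,
    csp_cutoff_ppm: float = 0.01,
    mass_cutoff: float = 0.95,
    scales=None,
) -> MatchReport:
    """Assemble the per-reference match report used by the CSV writer."""
    if scales is None:
        scales = resolve_scales(ref)
    best = best_matches(marginals, cutoff)
    det = csp_detection(marginals, ref, tgt, csp_cutoff_ppm, mass_cutoff, scales)
    est = csp_estimate(marginals, ref, tgt, scales)
    ref_labels = ref.labels()
    tgt_labels = tgt.labels()
    rows = []
    for b in best:
        r = b["reference_id"]
        if b["decision"] == NO_MATCH:
            tid, tlabel, csp_val = NO_MATCH, "", None
        else:
            tid = int(b["decision"])
            tlabel = tgt_labels[tid]
            csp_val = combined_csp(ref.peaks[r], tgt.peaks[tid], scales)
        mean = est["csp_mean"].iloc[r]
        sd = est["csp_sd"].iloc[r]
        rows.append(
            MatchReportRow(
                reference_id=r,
                reference_label=ref_labels[r],
                target_id=tid,
                target_label=tlabel,
                posterior_probability=b["probability"],
                csp_ppm=csp_val,
                csp_posterior_mass=float(det["csp_posterior_mass"].iloc[r]),
                csp_estimate_mean=None if math.isnan(mean) else float(mean),
                csp_estimate_sd=None if math.isnan(sd) else float(sd),
                tie=b["tie"],
            )
        )
    return MatchReport(rows=rows)


def evaluate(
    marginals: MatchMarginals,
    truth,
    true_csp_ppm: np.ndarray | None = None,
    prob_bin_edges: np.ndarray | None = None,
    csp_bin_edges: np.ndarray | None = None,
    detection_cutoff: float = 0.95,
) -> EvaluationResult:
    """Accuracy and completeness against ground truth, binned by posterior.

    ``truth`` maps each reference index to a target index or -1 for no
    match (array-like of length R).  A "made" match is a best decision
    on a target; accuracy per bin is correct/total among made matches
    falling in that posterior bin (empty bins hold NaN); cumulative
    accuracy and completeness sweep the cutoff upward.  The found/missed
    CSP histograms classify every true match as detected (correct with
    posterior >= ``detection_cutoff``) or missed.
    """
    best = best_matches(marginals, detection_cutoff)
    return evaluate_decisions(
        best, truth, true_csp_ppm, prob_bin_edges, csp_bin_edges, detection_cutoff
    )


def evaluate_decisions(
    best: list[dict],
    truth,
    true_csp_ppm: np.ndarray | None = None,
    prob_bin_edges: np.ndarray | None = None,
    csp_bin_edges: np.ndarray | None = None,
    detection_cutoff: float = 0.95,
) -> EvaluationResult:
    """As :func:`evaluate`, from an explicit per-reference decision list.

    ``best`` rows need keys ``reference_id``, ``decision`` (target index
    or NO_MATCH) and ``probability`` — the shape produced by
    :func:`best_matches` or read back from a match-report CSV.
    """
    n_ref = len(best)
    truth = np.asarray(truth, dtype=int)
    if truth.shape[0] != n_ref:
        raise ValueError("truth must cover every reference peak")
    if prob_bin_edges is None:
        prob_bin_edges = np.linspace(0.0, 1.0, 21)
    made = [b for b in best if b["decision"] != NO_MATCH]
    probs = np.array([b["probability"] for b in made])
    correct = np.array(
        [truth[b["reference_id"]] == b["decision"] for b in made], dtype=bool
    )
    n_true = int(np.sum(truth >= 0))
    rows = []
    for lo, hi in zip(prob_bin_edges[:-1], prob_bin_edges[1:]):
        top = hi >= prob_bin_edges[-1]
        in_bin = (probs >= lo) & ((probs <= hi) if top else (probs < hi))
        at_or_above = probs >= lo
        n_bin = int(in_bin.sum())
        acc = float(correct[in_bin].mean()) if n_bin else float("nan")
        n_cum = int(at_or_above.sum())
        cum_acc = float(correct[at_or_above].mean()) if n_cum else float("nan")
        cum_comp = float(correct[at_or_above].sum() / n_true) if n_true else float("nan")
        rows.append(
            {"bin_low": lo, "bin_high": hi, "n": n_bin, "accuracy": acc,
             "cum_accuracy": cum_acc, "cum_completeness": cum_comp}
        )
    bins = pd.DataFrame(rows)

    if csp_bin_edges is None:
        csp_bin_edges = np.logspace(-3, 0, 16)
    found = np.zeros(len(csp_bin_edges) - 1, dtype=int)
    missed = np.zeros(len(csp_bin_edges) - 1, dtype=int)
    if true_csp_ppm is not None:
        by_ref = {b["reference_id"]: b for b in best}
        for r in range(n_ref):
            if truth[r] < 0 or not np.isfinite(true_csp_ppm[r]):
                continue
            b = by_ref[r]
            detected = (
                b["decision"] != NO_MATCH
                and b["decision"] == truth[r]
                and b["probability"] >= detection_cutoff
            )
            idx = int(np.clip(np.searchsorted(csp_bin_edges, true_csp_ppm[r]) - 1,
                              0, len(found) - 1))
            (found if detected else missed)[idx] += 1
    return EvaluationResult(
        bins=bins, csp_found=found, csp_missed=missed,
        csp_bin_edges=np.asarray(csp_bin_edges, float),
    )
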