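"""Candidate filtering and reference-peak decision ordering.

Sampling assignments row by row works best when reference peaks that
compete for the same target peaks are decided consecutively, and peaks
that share no competition are decided independently.  This module builds,
for each reference peak, the set of plausible target candidates; derives
a reference–reference distance from candidate overlap; runs all-pairs
shortest paths (Floyd–Warshall) over that distance; and clusters/orders
the reference peaks by single-linkage agglomeration with optimal leaf
ordering of the dendrogram.

Because each hop distance is the reciprocal of an overlap count (<= 1),
any two reference peaks joined by a finite-distance path end up in the
same cluster at the 1.0 single-linkage threshold — the clusters are
exactly the connected components of the finite-distance graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.sparse.csgraph import floyd_warshall
from scipy.spatial.distance import squareform

from .model import DistanceMatrix, ModelParams, match_log_density, nomatch_log_density

__all__ = [
    "CandidateSet",
    "OrderingResult",
    "build_candidate_sets",
    "overlap_distance_matrix",
    "all_pairs_shortest_paths",
    "cluster_and_order",
    "build_ordering",
]

#: single-linkage cut height; hop distances are 1/overlap <= 1, so this
#: merges exactly the connected components of the finite-distance graph.
CLUSTER_DISTANCE_THRESHOLD = 1.0


@dataclass(frozen=True)
class CandidateSet:
    """Surviving target candidates for one reference peak.

    ``targets`` lists target indices; ``target_probs`` the matching
    normalized probabilities; ``nomatch_prob`` the probability of the
    always-present no-match pseudo-candidate.  Probabilities sum to 1.
    """

    reference_id: int
    targets: np.ndarray
    target_probs: np.ndarray
    nomatch_prob: float

    def __post_init__(self) -> None:
        total = float(np.sum(self.target_probs)) + self.nomatch_prob
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"candidate probabilities sum to {total}, not 1")


@dataclass(frozen=True)
class OrderingResult:
    """Partition of reference peaks into clusters plus the decision order.

    ``decision_order`` is a permutation of reference indices in which each
    cluster occupies a contiguous block; ``clusters`` lists each cluster's
    members in their decision order.
    """

    clusters: list[list[int]]
    decision_order: np.ndarray


def build_candidate_sets(
    D: DistanceMatrix,
    params: ModelParams,
    prob_ratio: float = 20.0,
) -> list[CandidateSet]:
    """Per-reference candidate targets after likelihood and ratio filtering.

    For each reference peak: targets whose matched density falls below the
    non-match density are eliminated; the survivors plus the no-match
    pseudo-candidate are normalized to probabilities; targets whose
    probability is below ``max_target_prob / prob_ratio`` are then
    dropped and the remainder renormalized.  The no-match candidate is
    never dropped.
    """
    log_match = match_log_density(D.values, params)  # (R, T)
    log_nm = nomatch_log_density(params)
    sets: list[CandidateSet] = []
    for r in range(D.n_ref):
        row = log_match[r]
        keep = np.flatnonzero(row >= log_nm)
        if keep.size:
            logs = np.concatenate([row[keep], [log_nm]])
            m = logs.max()
            p = np.exp(logs - m)
            p /= p.sum()
            tprobs, nm = p[:-1], p[-1]
            pmax = tprobs.max()
            keep2 = tprobs >= pmax / prob_ratio
            targets = keep[keep2]
            tprobs = tprobs[keep2]
            total = tprobs.sum() + nm
            tprobs = tprobs / total
            nm = nm / total
        else:
            targets = np.empty(0, dtype=int)
            tprobs = np.empty(0, dtype=float)
            nm = 1.0
        sets.append(
            CandidateSet(
                reference_id=r,
                targets=np.asarray(targets, dtype=int),
                target_probs=tprobs,
                nomatch_prob=float(nm),
            )
        )
    return sets


def overlap_distance_matrix(
    sets: list[CandidateSet], prob_ratio: float = 20.0
) -> np.ndarray:
    """Reference–reference distance = 1 / (number of shared, comparable candidates).

    A shared target counts toward overlap only when the two references'
    candidate probabilities for it are within ``prob_ratio`` of each
    other; zero overlap gives an infinite distance.  The no-match
    pseudo-candidate never counts.
    """
    n = len(sets)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    maps = [dict(zip(s.targets.tolist(), s.target_probs.tolist())) for s in sets]
    for i in range(n):
        for j in range(i + 1, n):
            overlap = 0
            small, large = (maps[i], maps[j]) if len(maps[i]) <= len(maps[j]) else (maps[j], maps[i])
            for t, p1 in small.items():
                p2 = large.get(t)
                if p2 is None:
                    continue
                hi, lo = (p1, p2) if p1 >= p2 else (p2, p1)
                if lo > 0 and hi / lo <= prob_ratio:
                    overlap += 1
            if overlap:
                dist[i, j] = dist[j, i] = 1.0 / overlap
    return dist


def all_pairs_shortest_paths(dist: np.ndarray) -> np.ndarray:
    """All-pairs shortest path distances (Floyd–Warshall) over the overlap graph."""
    dist = np.asarray(dist, dtype=float)
    if dist.shape[0] == 1:
        return dist.copy()
    return floyd_warshall(dist, directed=False)


def cluster_and_order(paths: np.ndarray) -> OrderingResult:
    """Single-linkage clustering (cut at 1.0) plus optimal leaf ordering.

    Disconnected pairs (infinite path distance) are mapped to a large
    finite placeholder above the cut height so they can never merge below
    the threshold, while the dendrogram — and hence the leaf order — is
    still defined over all reference peaks.
    """
    paths = np.asarray(paths, dtype=float)
    n = paths.shape[0]
    if n == 1:
        return OrderingResult(clusters=[[0]], decision_order=np.array([0]))
    finite = paths[np.isfinite(paths)]
    big = max(2.0, (finite.max() if finite.size else 1.0) * 2.0 + 2.0)
    filled = np.where(np.isfinite(paths), paths, big)
    np.fill_diagonal(filled, 0.0)
    condensed = squareform(filled, checks=False)
    Z = hierarchy.linkage(condensed, method="single")
    Z = hierarchy.optimal_leaf_ordering(Z, condensed)
    leaf_order = hierarchy.leaves_list(Z)
    labels = hierarchy.fcluster(Z, t=CLUSTER_DISTANCE_THRESHOLD, criterion="distance")
    leaf_pos = np.empty(n, dtype=int)
    leaf_pos[leaf_order] = np.arange(n)
    members: dict[int, list[int]] = {}
    for r, lab in enumerate(labels):
        members.setdefault(int(lab), []).append(r)
    clusters = [sorted(m, key=lambda r: leaf_pos[r]) for m in members.values()]
    clusters.sort(key=lambda c: min(c))
    decision_order = np.concatenate([np.asarray(c, dtype=int) for c in clusters])
    return OrderingResult(clusters=clusters, decision_order=decision_order)


def build_ordering(
    D: DistanceMatrix, params: ModelParams, prob_ratio: float = 20.0
) -> tuple[list[CandidateSet], OrderingResult]:
    """Convenience pipeline: candidate sets -> overlap graph -> clustered order."""
    sets = build_candidate_sets(D, params, prob_ratio)
    dist = overlap_distance_matrix(sets, prob_ratio)
    paths = all_pairs_shortest_paths(dist)
    return sets, cluster_and_order(paths)
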