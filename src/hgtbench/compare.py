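"""Similarity between inference methods and UPGMA clustering.

Two methods are compared by the Overlap Coefficient of their event sets —
|A ∩ B| / min(|A|, |B|) — maximized over all pairs of stringency levels, so
that nested sweeps (one method's inferences a subset of the other's at some
threshold pair) score 1. Events are keyed by (family, recipient branch),
ignoring donors, so implicit, explicit and parametric methods are mutually
comparable. 1 − maxOC is the distance fed to UPGMA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GainEvent, InferenceSet

__all__ = [
    "event_keys",
    "overlap_coefficient",
    "max_overlap_coefficient",
    "DistanceMatrix",
    "build_distance_matrix",
    "upgma",
]


def event_keys(events: list[GainEvent]) -> frozenset[tuple[str, str]]:
    """(family, recipient) keys of an event collection; donors ignored."""
    return frozenset((ev.family, ev.recipient) for ev in events)


def overlap_coefficient(a: frozenset | set, b: frozenset | set) -> float:
    if not a or not b:
        raise ValueError("overlap coefficient undefined for empty sets")
    return len(a & b) / min(len(a), len(b))


def max_overlap_coefficient(set1: InferenceSet, set2: InferenceSet) -> float:
    """Maximum Overlap Coefficient over all stringency-level pairs."""
    keys1 = [event_keys(evs) for evs in set1.levels.values() if evs]
    keys2 = [event_keys(evs) for evs in set2.levels.values() if evs]
    if not keys1 or not keys2:
        raise ValueError("all stringency levels empty")
    return max(overlap_coefficient(a, b) for a in keys1 for b in keys2)


@dataclass
class DistanceMatrix:
    methods: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries = 1 - maxOC

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.methods), len(self.methods)):
            raise ValueError("matrix shape does not match method list")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("distances must be in [0, 1]")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.methods.index(a), self.methods.index(b)])


def build_distance_matrix(sets: list[InferenceSet]) -> DistanceMatrix:
    if len(sets) < 2:
        raise ValueError("need at least two inference sets")
    names = [s.method for s in sets]
    if len(names) != len(set(names)):
        raise ValueError("method names must be unique")
    n = len(sets)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - max_overlap_coefficient(sets[i], sets[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(methods=names, values=values)


def upgma(matrix: DistanceMatrix) -> str:
    """UPGMA dendrogram as a newick string with branch lengths.

    Standard average linkage: repeatedly merge the closest pair of clusters;
    the distance from the merged cluster to any other is the size-weighted
    average; the merged node sits at height = merge distance / 2. Ties are
    broken by the lexicographically smallest pair of member tuples, so the
    output is deterministic.
    """
    # cluster id -> (sorted member tuple, size, height, newick fragment)
    clusters: dict[int, tuple[tuple[str, ...], int, float, str]] = {
        i: ((name,), 1, 0.0, name) for i, name in enumerate(matrix.methods)
    }
    dist: dict[frozenset[int], float] = {}
    ids = list(clusters)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            dist[frozenset((ids[i], ids[j]))] = float(matrix.values[i, j])
    next_id = len(ids)
    while len(clusters) > 1:
        best = None
        for pair, d in dist.items():
            a, b = sorted(pair, key=lambda c: clusters[c][0])
            key = (d, clusters[a][0], clusters[b][0])
            if best is None or key < best[0]:
                best = (key, a, b, d)
        _, a, b, d = best
        mem_a, size_a, h_a, nwk_a = clusters[a]
        mem_b, size_b, h_b, nwk_b = clusters[b]
        height = d / 2.0
        newick = (
            f"({nwk_a}:{height - h_a:.10g},{nwk_b}:{height - h_b:.10g})"
        )
        members = tuple(sorted(mem_a + mem_b))
        for other in list(clusters):
            if other in (a, b):
                continue
            d_a = dist.pop(frozenset((a, other)))
            d_b = dist.pop(frozenset((b, other)))
            dist[frozenset((next_id, other))] = (
                size_a * d_a + size_b * d_b
            ) / (size_a + size_b)
        dist.pop(frozenset((a, b)))
        del clusters[a], clusters[b]
        clusters[next_id] = (members, size_a + size_b, height, newick)
        next_id += 1
    (_, _, _, newick) = next(iter(clusters.values()))
    return newick + ";"
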