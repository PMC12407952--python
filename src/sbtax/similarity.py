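"""Alignment-free genome similarity: Jaccard, ANI, clustering, centroids.

The Jaccard similarity J = |A∩B| / |A∪B| of two canonical k-mer sets is
converted to an average nucleotide identity estimate with the Mash
transform

    ANI = (1 + (1/k) · ln(2J / (1+J))) · 100 ,

clamped to [0, 100].  The transform assumes a Poisson model of random
site substitutions; it requires the Jaccard *similarity* (J = 1 at
identity, giving ln(1) = 0 and ANI = 100), not the complementary
distance.  Filters can stand in for exact sets (popcount(AND)/popcount(OR)),
trading exactness for memory.

Species-style clustering is unweighted average-linkage agglomeration on
the distance 100−ANI; ties merge the lowest-index pair first so runs are
reproducible.  The cluster centroid is the member maximizing summed ANI
to all other members.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bloom import BloomFilter
from .kmers import KmerSignature, _check_same_k


def jaccard(a: KmerSignature | BloomFilter, b: KmerSignature | BloomFilter) -> float:
    """Jaccard similarity of two k-mer sets (exact) or filters (estimate).

    Two empty sets are treated as identical (similarity 1) with a warning.
    """
    if isinstance(a, KmerSignature) and isinstance(b, KmerSignature):
        _check_same_k([a, b])
        inter = np.intersect1d(a.kmers, b.kmers, assume_unique=True).size
        union = len(a) + len(b) - inter
    elif isinstance(a, BloomFilter) and isinstance(b, BloomFilter):
        if a.k and b.k and a.k != b.k:
            raise ValueError(f"mixed k-mer lengths: {a.k} vs {b.k}")
        inter = a.intersection_popcount(b)
        union = a.union_popcount(b)
    else:
        raise TypeError("jaccard needs two signatures or two filters")
    if union == 0:
        warnings.warn("Jaccard of two empty sets: returning similarity 1",
                      stacklevel=2)
        return 1.0
    return inter / union


def ani_from_jaccard(j: float, k: int, clamp: bool = True) -> float:
    """ANI percent from Jaccard similarity via the Mash transform.

    ``clamp=False`` returns the raw (possibly negative / -inf) value for
    diagnostics; j=0 maps to the clamp floor 0.
    """
    if not 0 <= j <= 1:
        raise ValueError(f"jaccard similarity out of [0,1]: {j}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if j == 0:
        raw = -math.inf
    else:
        raw = (1.0 + math.log(2.0 * j / (1.0 + j)) / k) * 100.0
    if not clamp:
        return raw
    return min(100.0, max(0.0, raw))


def ani(a: KmerSignature, b: KmerSignature) -> float:
    return ani_from_jaccard(jaccard(a, b), a.k)


@dataclass
class PairwiseMatrix:
    """Symmetric ANI-percent matrix over an ordered list of genome ids."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id list")

    def index(self, gid: str) -> int:
        return self.ids.index(gid)

    def ani_of(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def submatrix(self, subset: Sequence[str]) -> "PairwiseMatrix":
        idx = [self.index(g) for g in subset]
        return PairwiseMatrix(list(subset), self.values[np.ix_(idx, idx)])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PairwiseMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float))

    def to_long_tsv(self, path: str | Path) -> None:
        rows = [
            {"id1": self.ids[i], "id2": self.ids[j],
             "ani": float(self.values[i, j])}
            for i in range(len(self.ids)) for j in range(i + 1, len(self.ids))
        ]
        pd.DataFrame(rows, columns=["id1", "id2", "ani"]).to_csv(path, sep="\t", index=False)


def pairwise_ani(ids: Sequence[str], signatures: Sequence[KmerSignature]) -> PairwiseMatrix:
    """Symmetric pairwise ANI matrix; diagonal is 100."""
    if len(ids) != len(signatures):
        raise ValueError("ids and signatures differ in length")
    if len(ids) < 2:
        raise ValueError("need at least two signatures")
    k = _check_same_k(list(signatures))
    n = len(ids)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = ani_from_jaccard(
                jaccard(signatures[i], signatures[j]), k)
    return PairwiseMatrix(list(ids), values)


@dataclass
class ClusteringResult:
    partition: dict[str, int]
    linkage_trace: list[tuple[frozenset, frozenset, float]] = field(default_factory=list)

    def blocks(self) -> list[list[str]]:
        by_index: dict[int, list[str]] = {}
        for gid, idx in self.partition.items():
            by_index.setdefault(idx, []).append(gid)
        return [sorted(by_index[i]) for i in sorted(by_index)]


def average_linkage(matrix: PairwiseMatrix, cut: float) -> ClusteringResult:
    """Unweighted average-linkage agglomeration on distance 100−ANI.

    The dendrogram is cut so that a merge survives iff its height is at
    most ``100 − cut`` (merged clusters keep average ANI ≥ cut).  Ties
    merge the pair with the lowest indices first.
    """
    if not 0 < cut <= 100:
        raise ValueError("cut must be in (0, 100]")
    n = len(matrix.ids)
    dist = 100.0 - matrix.values.astype(float)
    active = list(range(n))                 # cluster representatives
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    trace: list[tuple[frozenset, frozenset, float]] = []
    labels = {i: i for i in range(n)}       # item -> current cluster id
    height_cut = 100.0 - cut
    next_id = n
    while len(active) > 1:
        best = min(
            ((d[(min(a, b), max(a, b))], a, b)
             for ai, a in enumerate(active) for b in active[ai + 1:]),
            key=lambda t: (t[0], t[1], t[2]),
        )
        h, a, b = best
        trace.append((
            frozenset(matrix.ids[i] for i in members[a]),
            frozenset(matrix.ids[i] for i in members[b]),
            h,
        ))
        merged = members[a] + members[b]
        na, nb = len(members[a]), len(members[b])
        new = next_id
        next_id += 1
        members[new] = merged
        for c in active:
            if c in (a, b):
                continue
            da = d[(min(a, c), max(a, c))]
            db = d[(min(b, c), max(b, c))]
            d[(min(new, c), max(new, c))] = (na * da + nb * db) / (na + nb)
        active = [c for c in active if c not in (a, b)] + [new]
        if h <= height_cut:
            for i in merged:
                labels[i] = new
    # renumber partitions 0..m-1 by order of first appearance
    seen: dict[int, int] = {}
    partition: dict[str, int] = {}
    for i, gid in enumerate(matrix.ids):
        root = labels[i]
        partition[gid] = seen.setdefault(root, len(seen))
    return ClusteringResult(partition, trace)


def centroid(member_ids: Sequence[str], matrix: PairwiseMatrix) -> str:
    """Cluster centroid: the member maximizing summed ANI to the others.

    Ties break to the lexicographically smallest id; a singleton returns
    its only member.  Raises KeyError for members absent from the matrix.
    """
    if not member_ids:
        raise ValueError("centroid of an empty cluster")
    for gid in member_ids:
        if gid not in matrix.ids:
            raise KeyError(f"genome {gid!r} not in pairwise matrix")
    if len(member_ids) == 1:
        return member_ids[0]
    idx = [matrix.index(g) for g in member_ids]
    sub = matrix.values[np.ix_(idx, idx)]
    sums = sub.sum(axis=1) - np.diag(sub)
    best_sum = sums.max()
    candidates = sorted(g for s, g in zip(sums, member_ids) if s == best_sum)
    return candidates[0]
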