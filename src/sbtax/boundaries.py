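"""Dynamic per-cluster ANI boundaries.

A cluster's boundaries are the minimum and maximum pairwise ANI among all
genomes under it — a threshold-free, data-driven membership criterion.
Computing them requires at least three member genomes; smaller clusters
borrow the mean boundaries of their computed siblings under the same
parent (falling back to the rank-wide mean, then to a configured rank
default), flagged ``inferred`` so they can be recomputed, and their
members re-audited, once the cluster grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence

from .kmers import RANKS, KmerSignature
from .similarity import PairwiseMatrix, ani, pairwise_ani

if TYPE_CHECKING:  # pragma: no cover
    from .database import Cluster, TaxonomyDB

# Default (min, max) ANI per rank, used only when an entire rank has no
# computed boundaries.  The species default follows the common 95%-ANI
# species convention; higher ranks relax progressively.
RANK_DEFAULT_BOUNDARIES: dict[str, tuple[float, float]] = {
    "kingdom": (50.0, 100.0),
    "phylum": (60.0, 100.0),
    "class": (65.0, 100.0),
    "order": (70.0, 100.0),
    "family": (75.0, 100.0),
    "genus": (85.0, 100.0),
    "species": (95.0, 100.0),
}


@dataclass(frozen=True)
class Boundaries:
    min_ani: float
    max_ani: float
    inferred: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.min_ani <= self.max_ani <= 100:
            raise ValueError(
                f"invalid boundaries ({self.min_ani}, {self.max_ani})")

    def contains(self, ani_value: float) -> bool:
        """Membership test: at least as similar as the least similar pair.

        One-sided on purpose — a query *more* similar than max_ani (e.g.
        identical to the centroid) is obviously a member.
        """
        return ani_value >= self.min_ani


def compute_boundaries(
    member_signatures: Sequence[KmerSignature] | None = None,
    *,
    member_ids: Optional[Sequence[str]] = None,
    matrix: Optional[PairwiseMatrix] = None,
) -> Boundaries:
    """Min/max pairwise ANI over the members of one cluster (≥3 required).

    Accepts either raw signatures (pairwise ANIs computed here) or member
    ids plus a precomputed matrix.
    """
    if matrix is not None:
        if member_ids is None:
            raise ValueError("member_ids required with a matrix")
        n = len(member_ids)
        if n < 3:
            raise ValueError(f"boundaries need >=3 members, got {n}")
        anis = [matrix.ani_of(a, b)
                for i, a in enumerate(member_ids) for b in member_ids[i + 1:]]
    else:
        if member_signatures is None:
            raise ValueError("need signatures or (member_ids, matrix)")
        n = len(member_signatures)
        if n < 3:
            raise ValueError(f"boundaries need >=3 members, got {n}")
        anis = [ani(member_signatures[i], member_signatures[j])
                for i in range(n) for j in range(i + 1, n)]
    return Boundaries(min(anis), max(anis), inferred=False)


def infer_boundaries(
    sibling_boundaries: Sequence[Boundaries],
    rank_boundaries: Sequence[Boundaries] = (),
    rank_default: tuple[float, float] = RANK_DEFAULT_BOUNDARIES["species"],
) -> Boundaries:
    """Boundaries for a small cluster, deduced from its surroundings.

    Mean min/max of the computed (non-inferred) siblings under the same
    parent; if none, the rank-wide mean over computed boundaries; if the
    whole rank lacks computed boundaries, the configured rank default.
    """
    for pool in (sibling_boundaries, rank_boundaries):
        computed = [b for b in pool if not b.inferred]
        if computed:
            return Boundaries(
                sum(b.min_ani for b in computed) / len(computed),
                sum(b.max_ani for b in computed) / len(computed),
                inferred=True,
            )
    return Boundaries(*rank_default, inferred=True)


def compute_all_boundaries(db: "TaxonomyDB") -> list[tuple[str, str]]:
    """(Re)compute boundaries for every cluster in the database.

    Returns the (rank, label) pairs whose boundaries transitioned from
    inferred (or absent after growth) to computed — the clusters whose
    members need re-auditing.
    """
    transitioned: list[tuple[str, str]] = []
    defaults = {r: tuple(v) for r, v in db.manifest["rank_defaults"].items()}
    for rank in RANKS:
        for label in sorted(db.clusters[rank]):
            cluster = db.clusters[rank][label]
            if len(cluster.genomes) >= 3 and db.matrix is not None:
                was_inferred = cluster.boundaries is None or cluster.boundaries.inferred
                cluster.boundaries = compute_boundaries(
                    member_ids=sorted(cluster.genomes), matrix=db.matrix)
                if was_inferred:
                    transitioned.append((rank, label))
    # second pass: inference for small clusters, siblings now computed
    for rank in RANKS:
        rank_pool = [
            c.boundaries for _, c in sorted(db.clusters[rank].items())
            if c.boundaries is not None
        ]
        for label in sorted(db.clusters[rank]):
            cluster = db.clusters[rank][label]
            if len(cluster.genomes) >= 3 and db.matrix is not None:
                continue
            sibs = [
                c.boundaries for c in db.siblings(rank, label)
                if c.boundaries is not None
            ]
            cluster.boundaries = infer_boundaries(
                sibs, rank_pool, defaults[rank])
    return transitioned


def audit_boundaries(
    db: "TaxonomyDB",
    recomputed: Optional[Sequence[tuple[str, str]]] = None,
) -> list[tuple[str, str]]:
    """MAGs that fell out of their cluster's newly computed boundaries.

    For every cluster whose boundaries went from inferred to computed
    (``recomputed``; all computed clusters when omitted), list previously
    assigned MAGs whose ANI to the cluster centroid is now below min_ani —
    the re-clustering queue.
    """
    if db.matrix is None:
        return []
    if recomputed is None:
        recomputed = [
            (rank, label)
            for rank in RANKS
            for label, c in sorted(db.clusters[rank].items())
            if c.boundaries is not None and not c.boundaries.inferred
        ]
    violations: list[tuple[str, str]] = []
    for rank, label in recomputed:
        cluster = db.clusters[rank][label]
        if cluster.boundaries is None or cluster.boundaries.inferred:
            continue
        anchor = cluster.centroid_id
        if anchor is None:
            continue
        for gid in sorted(cluster.genomes):
            if gid == anchor or db.records[gid].genome_type != "MAG":
                continue
            if not cluster.boundaries.contains(db.matrix.ani_of(gid, anchor)):
                violations.append((label, gid))
    return violations
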