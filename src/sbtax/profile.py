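"""Top-down taxonomic profiling of query genomes.

A query's canonical k-mers are probed against the kingdom root, then
against candidate cluster roots rank by rank down to species.  At each
rank the best match count c* is found and every candidate within 25% of
it (count ≥ 0.75·c*) is retained — the expansion guards against
horizontal gene transfer pulling the true lineage out of the beam — and
only retained subtrees are descended.  At the species rank the query's
ANI to the centroid of the closest species decides membership against the
species' dynamic boundaries; the best-matching leaf genome is reported as
the closest strain.  A query matching less than the kingdom floor
(default 1% of its k-mers) at the root is unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .database import TaxonomyDB
from .kmers import RANKS, KmerSignature
from .similarity import ani
from .taxonomy import Lineage

STATUSES = ("assigned", "partial", "unassigned")


@dataclass
class RankEntry:
    rank: str
    label: str
    matched_kmers: int
    matched_fraction: float
    centroid_ani: Optional[float] = None
    within_boundaries: Optional[bool] = None


@dataclass
class Profile:
    query_id: str
    entries: list[RankEntry] = field(default_factory=list)  # kingdom → deepest
    closest_genome: Optional[str] = None
    status: str = "unassigned"

    def entry(self, rank: str) -> Optional[RankEntry]:
        for e in self.entries:
            if e.rank == rank:
                return e
        return None

    @property
    def species(self) -> Optional[str]:
        e = self.entry("species")
        return e.label if e else None


def profile_genome(
    query_id: str,
    query: KmerSignature,
    db: TaxonomyDB,
    expansion: Optional[float] = None,
    kingdom_floor: Optional[float] = None,
) -> Profile:
    """Profile one query genome through the rank hierarchy."""
    if len(query) == 0:
        raise ValueError("empty query signature")
    if not db.records:
        raise ValueError("empty database")
    if expansion is None:
        expansion = db.manifest["expansion"]
    if kingdom_floor is None:
        kingdom_floor = db.manifest["kingdom_floor"]
    n_query = len(query)
    profile = Profile(query_id=query_id)

    candidates = sorted(db.clusters["kingdom"])
    for rank_index, rank in enumerate(RANKS):
        counts = {
            label: db.trees[rank][label].filter.count_hits(query)
            for label in candidates
        }
        best_count = max(counts.values(), default=0)
        if rank == "kingdom":
            # correct for Bloom-filter false positives before applying the
            # floor: a filter at density d reports ~d·|Q| spurious hits even
            # for a query sharing nothing with the root
            corrected = {}
            for label, c in counts.items():
                d = db.trees[rank][label].filter.density()
                corrected[label] = max(0.0, (c - n_query * d) / (1.0 - d)) if d < 1 else 0.0
            if max(corrected.values(), default=0.0) < kingdom_floor * n_query:
                best_label = min((lab for lab in counts), default="")
                if best_label:
                    profile.entries.append(RankEntry(
                        rank, best_label, counts[best_label],
                        counts[best_label] / n_query))
                profile.status = "unassigned"
                return profile
        if best_count == 0:
            break
        retained = sorted(
            lab for lab, c in counts.items() if c >= (1.0 - expansion) * best_count)
        # the closest cluster: centroid ANI decides at species, count above
        if rank == "species":
            scored = []
            for lab in retained:
                anchor = db.clusters[rank][lab].centroid_id
                scored.append((ani(query, db.signatures[anchor]), counts[lab], lab))
            scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
            centroid_ani, count, label = scored[0]
        else:
            label = min(
                (lab for lab in retained if counts[lab] == best_count))
            anchor = db.clusters[rank][label].centroid_id
            centroid_ani = ani(query, db.signatures[anchor])
            count = counts[label]
        cluster = db.clusters[rank][label]
        within = (cluster.boundaries.contains(centroid_ani)
                  if cluster.boundaries is not None else None)
        profile.entries.append(RankEntry(
            rank, label, count, count / n_query, centroid_ani, within))
        if rank == "species":
            # closest strain among the chosen species' member genomes
            strain_counts = [
                (leaf.filter.count_hits(query), leaf.payload)
                for leaf in db.trees["species"][label].leaves()
            ]
            best_strain_count = max(cnt for cnt, _ in strain_counts)
            profile.closest_genome = min(
                payload for cnt, payload in strain_counts if cnt == best_strain_count)
            profile.status = "assigned" if within else "partial"
            return profile
        candidates = sorted(
            {child for lab in retained for child in db.clusters[rank][lab].children})
        if not candidates:
            break
    profile.status = "partial" if profile.entries else "unassigned"
    return profile


def partial_lineage(profile: Profile, db: TaxonomyDB) -> Lineage:
    """Deepest lineage prefix whose cluster boundaries the query satisfied.

    Walks species→kingdom and takes the first (deepest) rank whose verdict
    is within-boundaries; the prefix is the selected cluster's own lineage,
    so it is always a consistent chain.  A shallower failure does not mask
    a deeper success: the centroid of a broad cluster (e.g. the kingdom)
    can sit in a distant subtree, while the genus-level verdict is the
    informative one.
    """
    for i in range(len(RANKS) - 1, -1, -1):
        e = profile.entry(RANKS[i])
        if e is not None and e.within_boundaries:
            return db.lineage_of_cluster(e.rank, e.label).prefix(i + 1)
    return Lineage.of()


def profiles_to_tsv(profiles: list[Profile], path: str | Path) -> None:
    """One row per query × rank."""
    rows = []
    for p in profiles:
        for e in p.entries:
            rows.append({
                "query_id": p.query_id,
                "rank": e.rank,
                "closest_label": e.label,
                "matched_kmers": e.matched_kmers,
                "matched_fraction": f"{e.matched_fraction:.6f}",
                "centroid_ani": ("" if e.centroid_ani is None
                                 else f"{e.centroid_ani:.6f}"),
                "within_boundaries": ("" if e.within_boundaries is None
                                      else str(e.within_boundaries).lower()),
                "closest_strain": p.closest_genome or "",
                "status": p.status,
            })
    pd.DataFrame(rows, columns=["query_id", "rank", "closest_label", "matched_kmers",
                                "matched_fraction", "centroid_ani",
                                "within_boundaries", "closest_strain", "status"]
                 ).to_csv(path, sep="\t", index=False)


def boundaries_to_tsv(db: TaxonomyDB, path: str | Path) -> None:
    """Boundaries report: label, rank, n_genomes, min_ani, max_ani, inferred."""
    rows = []
    for rank in RANKS:
        for label in sorted(db.clusters[rank]):
            c = db.clusters[rank][label]
            b = c.boundaries
            rows.append({
                "label": label, "rank": rank, "n_genomes": len(c.genomes),
                "min_ani": "" if b is None else f"{b.min_ani:.6f}",
                "max_ani": "" if b is None else f"{b.max_ani:.6f}",
                "inferred": "" if b is None else str(b.inferred).lower(),
            })
    pd.DataFrame(rows, columns=["label", "rank", "n_genomes", "min_ani",
                                "max_ani", "inferred"]).to_csv(
        path, sep="\t", index=False)
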