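"""Incremental database update and reference-set refinement.

An update batch flows through: optional quality gate → dereplication
(greedy, database genomes first, default 99% ANI) → per-genome profiling
with immediate average-linkage co-assignment at the hit species' boundary
→ definition of new ``MSBT``-labelled clusters for genomes outside every
boundary (grouped by their partial lineages, split at sibling-mean
boundaries, rank by rank down to species) → taxonomy inheritance /
majority voting when the batch carries reference genomes → local rebuild
of the affected branches → boundary re-audit.

``refine_references`` is the standalone reclassification procedure:
average-linkage clustering of reference genomes at a fixed ANI cut
(default 95%), majority-vote labelling, misclassification and vanished-
label reporting, and ``|cN`` clade numbering when one label wins several
clusters.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .boundaries import audit_boundaries, compute_all_boundaries, infer_boundaries
from .database import TaxonomyDB
from .kmers import RANKS, KmerSignature, count_distinct, _round_up64
from .profile import partial_lineage, profile_genome
from .similarity import PairwiseMatrix, ani, average_linkage, pairwise_ani
from .taxonomy import GenomeRecord, Lineage, quality_tier

import numpy as np


@dataclass
class BatchGenome:
    genome_id: str
    signature: KmerSignature
    genome_type: str = "MAG"
    lineage: Optional[Lineage] = None     # reference genomes only
    completeness: Optional[float] = None
    contamination: Optional[float] = None


@dataclass
class UpdateBatch:
    genomes: list[BatchGenome]
    dereplication_threshold: float = 99.0
    quality_gate: bool = False


@dataclass
class UpdateReport:
    assigned: dict[str, str] = field(default_factory=dict)        # genome -> species
    new_clusters: dict[str, list[tuple[str, int]]] = field(
        default_factory=lambda: {r: [] for r in RANKS})           # rank -> (label, n)
    dereplicated: list[tuple[str, str, float]] = field(default_factory=list)
    excluded_quality: list[str] = field(default_factory=list)
    unassigned: list[str] = field(default_factory=list)
    relabeled_clusters: list[tuple[str, str]] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)
    rebuilt_branches: list[str] = field(default_factory=list)
    reclustering_queue: list[tuple[str, str]] = field(default_factory=list)

    def to_document(self) -> dict:
        return {
            "assigned": dict(sorted(self.assigned.items())),
            "new_clusters": {r: [list(t) for t in v]
                             for r, v in self.new_clusters.items()},
            "dereplicated": [list(t) for t in self.dereplicated],
            "excluded_quality": self.excluded_quality,
            "unassigned": self.unassigned,
            "relabeled_clusters": [list(t) for t in self.relabeled_clusters],
            "conflicts": self.conflicts,
            "rebuilt_branches": self.rebuilt_branches,
            "reclustering_queue": [list(t) for t in self.reclustering_queue],
        }


# ---------------------------------------------------------------------------
# dereplication

def dereplicate(
    batch: Sequence[BatchGenome],
    db_entries: Sequence[tuple[str, KmerSignature]],
    threshold: float = 99.0,
) -> tuple[list[BatchGenome], list[tuple[str, str, float]]]:
    """Greedy first-kept dereplication at an ANI threshold.

    Database genomes are kept unconditionally and considered first, then
    batch genomes in input order; a genome is dropped iff its ANI to an
    already-kept genome is >= threshold, recording the keeper (highest
    ANI, ties to the lexicographically smaller id).
    """
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    kept_entries: list[tuple[str, KmerSignature]] = list(db_entries)
    kept: list[BatchGenome] = []
    dropped: list[tuple[str, str, float]] = []
    for genome in batch:
        hits = []
        for kid, ksig in kept_entries:
            a = ani(genome.signature, ksig)
            if a >= threshold:
                hits.append((a, kid))
        if hits:
            hits.sort(key=lambda t: (-t[0], t[1]))
            dropped.append((genome.genome_id, hits[0][1], hits[0][0]))
        else:
            kept.append(genome)
            kept_entries.append((genome.genome_id, genome.signature))
    return kept, dropped


# ---------------------------------------------------------------------------
# assignment

def assign_or_queue(
    kept: Sequence[BatchGenome],
    db: TaxonomyDB,
    batch_matrix: Optional[PairwiseMatrix],
) -> tuple[dict[str, str], list[tuple[BatchGenome, Lineage]], list[str]]:
    """Profile batch genomes; assign to species or queue with partial lineage.

    On every species hit an average-linkage clustering of the batch's
    pairwise ANI matrix, cut at that species' minimum boundary, co-assigns
    the whole block of the hit genome.  Genomes failing every species
    boundary are queued carrying the deepest rank they satisfied; genomes
    below the kingdom floor are unassigned.
    """
    assignments: dict[str, str] = {}
    queued: list[tuple[BatchGenome, Lineage]] = []
    unassigned: list[str] = []
    by_id = {g.genome_id: g for g in kept}
    for genome in kept:
        if genome.genome_id in assignments:
            continue
        profile = profile_genome(genome.genome_id, genome.signature, db)
        if profile.status == "assigned":
            species = profile.species
            assignments[genome.genome_id] = species
            if batch_matrix is not None and len(kept) > 1:
                cut = db.clusters["species"][species].boundaries.min_ani
                clustering = average_linkage(batch_matrix, cut)
                block_id = clustering.partition[genome.genome_id]
                for other_id, b in clustering.partition.items():
                    if (b == block_id and other_id in by_id
                            and other_id not in assignments):
                        assignments[other_id] = species
        elif profile.status == "unassigned":
            unassigned.append(genome.genome_id)
        else:
            queued.append((genome, partial_lineage(profile, db)))
    # a queued genome may have been co-assigned by a later hit
    still_queued = [(g, pl) for g, pl in queued if g.genome_id not in assignments]
    return assignments, still_queued, unassigned


# ---------------------------------------------------------------------------
# new cluster definition

def define_new_clusters(
    queued: Sequence[tuple[BatchGenome, Lineage]],
    db: TaxonomyDB,
    batch_matrix: Optional[PairwiseMatrix],
) -> tuple[dict[str, Lineage], dict[str, list[tuple[str, int]]]]:
    """Create MSBT-labelled clusters for genomes outside every boundary.

    Genomes are grouped by identical partial lineage; at each group's
    first unfilled rank the boundary is inferred from the siblings under
    the same parent (same machinery as infer_boundaries), the group's ANI
    submatrix is cut at that boundary's minimum, and every block becomes a
    new cluster, recursing rank by rank down to species.
    """
    defaults = {r: tuple(v) for r, v in db.manifest["rank_defaults"].items()}
    lineages: dict[str, Lineage] = {}
    created: dict[str, list[tuple[str, int]]] = {r: [] for r in RANKS}

    def rank_pool(rank: str) -> list:
        return [c.boundaries for _, c in sorted(db.clusters[rank].items())
                if c.boundaries is not None]

    def sibling_pool(rank: str, parent: Optional[str]) -> list:
        if parent is None:
            return rank_pool(rank)
        return [c.boundaries for _, c in sorted(db.clusters[rank].items())
                if c.parent == parent and c.boundaries is not None]

    def descend(prefix: Lineage, member_ids: list[str]) -> None:
        depth = prefix.depth
        rank = RANKS[depth]
        parent = prefix.labels[depth - 1] if depth else None
        boundary = infer_boundaries(
            sibling_pool(rank, parent), rank_pool(rank), defaults[rank])
        if len(member_ids) == 1 or batch_matrix is None:
            blocks = [sorted(member_ids)]
        else:
            sub = batch_matrix.submatrix(sorted(member_ids))
            blocks = average_linkage(sub, boundary.min_ani).blocks()
        for block in sorted(blocks, key=lambda b: b[0]):
            label = db.allocate_msbt_label()
            created[rank].append((label, len(block)))
            new_prefix = prefix.with_rank(rank, label)
            if rank == "species":
                for gid in block:
                    lineages[gid] = new_prefix
            else:
                descend(new_prefix, block)

    groups: dict[str, list[str]] = {}
    prefix_by_key: dict[str, Lineage] = {}
    for genome, prefix in queued:
        key = prefix.serialize()
        groups.setdefault(key, []).append(genome.genome_id)
        prefix_by_key[key] = prefix
    # deepest (most specific) partial lineages first, then lexicographic
    for key in sorted(groups, key=lambda s: (-prefix_by_key[s].depth, s)):
        descend(prefix_by_key[key], sorted(groups[key]))
    return lineages, created


# ---------------------------------------------------------------------------
# reference integration (majority voting / inheritance)

def _relabel_cluster(db: TaxonomyDB, rank: str, old: str, new: str) -> None:
    cluster = db.clusters[rank].pop(old)
    cluster.label = new
    db.clusters[rank][new] = cluster
    if cluster.parent is not None:
        parent_rank = RANKS[RANKS.index(rank) - 1]
        siblings = db.clusters[parent_rank][cluster.parent].children
        siblings[siblings.index(old)] = new
        siblings.sort()
    child_rank = RANKS[RANKS.index(rank) + 1] if rank != "species" else None
    if child_rank:
        for child in cluster.children:
            db.clusters[child_rank][child].parent = new
    for gid in cluster.genomes:
        record = db.records[gid]
        record.taxonomy = record.taxonomy.with_rank(rank, new)
    if old in db.trees[rank]:
        db.trees[rank][new] = db.trees[rank].pop(old)
    sizes = db.manifest["plan"]["sizes"][rank]
    if old in sizes:
        sizes[new] = sizes.pop(old)


def integrate_references(db: TaxonomyDB) -> tuple[list[tuple[str, str]], list[str]]:
    """Re-label clusters from their member reference genomes' taxonomies.

    Unknown clusters containing references inherit the majority reference
    lineage (losing their unknown labels wherever no known ancestor
    conflicts); known clusters take the most frequent reference taxonomy,
    ties broken lexicographically.  Conflicting rank structure is recorded
    and the cluster's existing parent lineage wins.
    """
    relabeled: list[tuple[str, str]] = []
    conflicts: list[str] = []
    for species_label in sorted(db.clusters["species"]):
        cluster = db.clusters["species"][species_label]
        originals: list[Lineage] = []
        for gid in sorted(cluster.genomes):
            record = db.records[gid]
            original = record.extra.get("original_lineage")
            if record.genome_type == "reference" and original:
                originals.append(Lineage(tuple(original)) if isinstance(original, (list, tuple))
                                 else original)
        if not originals:
            continue
        votes = Counter(lin["species"] for lin in originals)
        top = max(votes.values())
        winner_species = min(s for s, n in votes.items() if n == top)
        winner = next(lin for lin in originals if lin["species"] == winner_species)
        current = db.lineage_of_cluster("species", species_label)
        # walk species → kingdom, relabelling unknown ranks from the winner
        label_at = {r: current[r] for r in RANKS}
        for rank in reversed(RANKS):
            have, want = label_at[rank], winner[rank]
            if have == want:
                continue
            cluster_r = db.clusters[rank][have]
            if cluster_r.is_known:
                if rank != "species":
                    conflicts.append(
                        f"cluster {label_at['species']} inherits {want!r} at {rank} "
                        f"but sits under known {have!r}; parent lineage wins")
                    break
                # known species, majority vote decided a different label
            if want in db.clusters[rank]:
                conflicts.append(
                    f"cannot relabel {have!r} to {want!r} at {rank}: label in use")
                continue
            _relabel_cluster(db, rank, have, want)
            relabeled.append((have, want))
            label_at[rank] = want
    return relabeled, conflicts


# ---------------------------------------------------------------------------
# branch rebuild

def rebuild_branch(db: TaxonomyDB, species_labels: Sequence[str]) -> list[str]:
    """Rebuild the SBTs along the lineage paths of the given species.

    Species trees are rebuilt from member genome filters, then their genus
    trees from species roots, and so on to the kingdom; untouched branches
    are left bit-identical.  Returns the rebuilt lineages.
    """
    affected: set[tuple[str, str]] = set()
    lineages = []
    for label in sorted(set(species_labels)):
        lineage = db.lineage_of_cluster("species", label)
        lineages.append(lineage.serialize())
        for rank in RANKS:
            affected.add((rank, lineage[rank]))
    for rank in reversed(RANKS):
        for r, label in sorted(affected):
            if r == rank:
                db.build_cluster_tree(rank, label)
    return lineages


def _ensure_plan_sizes(db: TaxonomyDB) -> None:
    """Plan filter sizes for clusters created since the last build."""
    inflation = db.manifest["inflation"]
    min_occ = db.manifest["min_occurrence"]
    for rank in RANKS:
        sizes = db.manifest["plan"]["sizes"][rank]
        for label in sorted(db.clusters[rank]):
            if label not in sizes:
                sigs = [db.signatures[g]
                        for g in sorted(db.clusters[rank][label].genomes)]
                raw = count_distinct(sigs, min_occ)
                sizes[label] = _round_up64(int(np.ceil(raw * (1.0 + inflation))))
                db.manifest["plan"]["raw"][rank][label] = raw


# ---------------------------------------------------------------------------
# orchestration

def apply_update(db: TaxonomyDB, batch: UpdateBatch) -> UpdateReport:
    """Run the full update pipeline on a database, in place."""
    report = UpdateReport()
    genomes = list(batch.genomes)
    if batch.quality_gate:
        passed = []
        for g in genomes:
            if (g.completeness is not None and g.contamination is not None
                    and quality_tier(g.completeness, g.contamination) == "fail"):
                report.excluded_quality.append(g.genome_id)
            else:
                passed.append(g)
        genomes = passed
    for g in genomes:
        if g.genome_id in db.records:
            raise ValueError(f"batch genome id {g.genome_id} already in database")
        if g.signature.k != db.k:
            raise ValueError(f"batch genome {g.genome_id}: k={g.signature.k} != {db.k}")
    db_entries = [(gid, db.signatures[gid]) for gid in sorted(db.records)]
    kept, dropped = dereplicate(genomes, db_entries, batch.dereplication_threshold)
    report.dereplicated = dropped
    if not kept:
        return report
    # deterministic processing order: descending signature size, then id
    kept.sort(key=lambda g: (-len(g.signature), g.genome_id))
    batch_matrix = None
    if len(kept) > 1:
        ids = [g.genome_id for g in kept]
        batch_matrix = pairwise_ani(ids, [g.signature for g in kept])
    assignments, queued, unassigned = assign_or_queue(kept, db, batch_matrix)
    report.unassigned = unassigned

    def attach(genome: BatchGenome, lineage) -> None:
        extra = {}
        if genome.genome_type == "reference" and genome.lineage is not None:
            extra["original_lineage"] = genome.lineage
        record = GenomeRecord(
            metasbt_id=db.allocate_genome_id(), genome_id=genome.genome_id,
            genome_type=genome.genome_type, taxonomy=lineage,
            completeness=genome.completeness, contamination=genome.contamination,
            extra=extra)
        db.attach_genome(record, genome.signature)
        affected_species.add(lineage["species"])

    affected_species: set[str] = set()
    by_id = {g.genome_id: g for g in kept}
    for gid in sorted(assignments):
        attach(by_id[gid], db.lineage_of_cluster("species", assignments[gid]))
    # first-pass growth widens cluster boundaries (min is non-increasing),
    # so genomes that missed a boundary by a hair get one more look before
    # new clusters are minted
    if queued and assignments:
        db.refresh_matrix()
        compute_all_boundaries(db)
        db.refresh_centroids()
        still_queued = []
        for g, _ in queued:
            profile = profile_genome(g.genome_id, g.signature, db)
            if profile.status == "assigned":
                assignments[g.genome_id] = profile.species
                attach(g, db.lineage_of_cluster("species", profile.species))
            else:
                still_queued.append((g, partial_lineage(profile, db)))
        queued = still_queued
    report.assigned = assignments
    new_lineages, created = define_new_clusters(queued, db, batch_matrix)
    report.new_clusters = created
    for gid in sorted(new_lineages):
        attach(by_id[gid], new_lineages[gid])
    relabeled, conflicts = integrate_references(db)
    report.relabeled_clusters = relabeled
    report.conflicts = conflicts
    rename = dict(relabeled)
    affected_species = {rename.get(s, s) for s in affected_species}
    db.refresh_matrix()
    transitioned = compute_all_boundaries(db)
    db.refresh_centroids()
    _ensure_plan_sizes(db)
    report.rebuilt_branches = rebuild_branch(db, sorted(affected_species))
    report.reclustering_queue = audit_boundaries(db, transitioned)
    return report


# ---------------------------------------------------------------------------
# reference-set refinement (reclassification)

@dataclass
class RefineResult:
    cluster_labels: list[str]                       # final label per cluster
    partition: dict[str, int]                       # genome -> cluster index
    relabeled: list[tuple[str, str, str]]           # genome, original, new label
    clades: dict[str, list[str]]                    # base label -> clade labels
    vanished: list[str]                             # labels that won no cluster

    @property
    def misclassified(self) -> list[str]:
        return sorted(g for g, _, _ in self.relabeled)


def refine_references(
    ids: Sequence[str],
    signatures: Sequence[KmerSignature],
    labels: dict[str, str],
    cut: float = 95.0,
) -> RefineResult:
    """Reclassify reference genomes by de novo ANI clustering.

    Average-linkage at ``cut`` (default the 95%-ANI species convention),
    majority-vote label per cluster (ties lexicographic), misclassified
    genomes reported, clusters sharing a winning label numbered ``|cN`` in
    descending-size order, and labels winning no cluster listed as
    vanished.
    """
    if len(ids) < 2:
        raise ValueError("refinement needs at least two genomes")
    matrix = pairwise_ani(ids, signatures)
    clustering = average_linkage(matrix, cut)
    blocks = clustering.blocks()
    winners: list[str] = []
    for block in blocks:
        votes = Counter(labels[g] for g in block)
        top = max(votes.values())
        winners.append(min(lab for lab, n in votes.items() if n == top))
    # clade numbering for duplicated winners, descending block size
    final = list(winners)
    clades: dict[str, list[str]] = {}
    for label in sorted(set(winners)):
        indices = [i for i, w in enumerate(winners) if w == label]
        if len(indices) < 2:
            continue
        indices.sort(key=lambda i: (-len(blocks[i]), blocks[i][0]))
        clades[label] = []
        for n, i in enumerate(indices, start=1):
            final[i] = f"{label}|c{n}"
            clades[label].append(final[i])
    relabeled = []
    partition: dict[str, int] = {}
    for i, block in enumerate(blocks):
        for g in block:
            partition[g] = i
            if labels[g] != winners[i]:
                relabeled.append((g, labels[g], final[i]))
    vanished = sorted(set(labels.values()) - set(winners))
    return RefineResult(final, partition, sorted(relabeled), clades, vanished)
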