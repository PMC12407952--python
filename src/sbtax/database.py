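"""The taxonomy database: a 7-rank forest of clusters, each owning an SBT.

Every genome belongs to exactly one species cluster; species roll up into
genera, families, orders, classes, phyla and a single kingdom, and each
cluster's tree root filter is the union of all descendant genome k-mers.
The database keeps, per genome, the exact canonical k-mer signature (so
child filters can be re-populated into the differently-sized filters of
higher ranks without loss), the pairwise ANI matrix over all genomes, and
per-cluster ANI boundaries and centroid genomes.
"""

from __future__ import annotations

import json
import re
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bloom import BloomFilter, FormatError, filter_from_signature
from .boundaries import Boundaries, RANK_DEFAULT_BOUNDARIES, compute_all_boundaries
from .kmers import (RANKS, BfSizingPlan, KmerSignature, plan_bf_sizes,
                    union_signature)
from .sbt import SBTNode, build_tree, load_tree, save_tree
from .similarity import PairwiseMatrix, centroid, pairwise_ani
from .taxonomy import GenomeRecord, Lineage, UNKNOWN_LABEL_RE, parse_lineage

DB_FORMAT_VERSION = 1
SIG_MAGIC = b"KSIG"
_SIG_HEADER = struct.Struct("<4sHHQ")  # magic, version, k, count


class TaxonomyError(ValueError):
    """Inconsistent rank structure (orphan children, conflicting parents)."""


class SaturationError(RuntimeError):
    """A rebuilt filter exceeded the configured density ceiling."""


@dataclass
class Cluster:
    label: str
    rank: str
    parent: Optional[str] = None
    children: list[str] = field(default_factory=list)   # child cluster labels
    genomes: list[str] = field(default_factory=list)    # genome ids under it
    boundaries: Optional[Boundaries] = None
    centroid_id: Optional[str] = None
    size_bits: int = 0

    @property
    def is_known(self) -> bool:
        return not UNKNOWN_LABEL_RE.match(self.label)


@dataclass
class TaxonomyDB:
    manifest: dict
    records: dict[str, GenomeRecord] = field(default_factory=dict)
    signatures: dict[str, KmerSignature] = field(default_factory=dict)
    clusters: dict[str, dict[str, Cluster]] = field(
        default_factory=lambda: {r: {} for r in RANKS})
    trees: dict[str, dict[str, SBTNode]] = field(
        default_factory=lambda: {r: {} for r in RANKS})
    matrix: Optional[PairwiseMatrix] = None

    # -- manifest shortcuts -------------------------------------------------

    @property
    def k(self) -> int:
        return self.manifest["k"]

    @property
    def num_hashes(self) -> int:
        return self.manifest["num_hashes"]

    @property
    def hash_seed(self) -> int:
        return self.manifest["hash_seed"]

    def allocate_msbt_label(self) -> str:
        n = self.manifest["msbt_counter"]
        self.manifest["msbt_counter"] = n + 1
        return f"MSBT{n}"

    def allocate_genome_id(self) -> str:
        n = self.manifest["genome_counter"]
        self.manifest["genome_counter"] = n + 1
        return f"SBTX{n:06d}"

    # -- structure ----------------------------------------------------------

    def cluster(self, rank: str, label: str) -> Cluster:
        return self.clusters[rank][label]

    def lineage_of_cluster(self, rank: str, label: str) -> Lineage:
        labels = []
        current = label
        for r in reversed(RANKS[: RANKS.index(rank) + 1]):
            labels.append(current)
            current = self.clusters[r][labels[-1]].parent
        return Lineage.of(*reversed(labels))

    def siblings(self, rank: str, label: str) -> list[Cluster]:
        me = self.clusters[rank][label]
        return [
            c for lab, c in sorted(self.clusters[rank].items())
            if lab != label and c.parent == me.parent
        ]

    def union_signature_of(self, rank: str, label: str) -> KmerSignature:
        genomes = self.clusters[rank][label].genomes
        return union_signature([self.signatures[g] for g in sorted(genomes)])

    def attach_genome(self, record: GenomeRecord, sig: KmerSignature) -> None:
        """Register a genome and thread it through its (full) lineage clusters."""
        lineage = record.taxonomy
        if lineage is None or not lineage.is_full():
            raise TaxonomyError(f"genome {record.genome_id} lacks a full 7-rank lineage")
        gid = record.genome_id
        if gid in self.records:
            raise TaxonomyError(f"duplicate genome id {gid}")
        self.records[gid] = record
        self.signatures[gid] = sig
        parent = None
        for rank in RANKS:
            label = lineage[rank]
            cluster = self.clusters[rank].get(label)
            if cluster is None:
                cluster = Cluster(label=label, rank=rank, parent=parent)
                self.clusters[rank][label] = cluster
                if parent is not None:
                    parent_cluster = self.clusters[RANKS[RANKS.index(rank) - 1]][parent]
                    if label not in parent_cluster.children:
                        parent_cluster.children.append(label)
                        parent_cluster.children.sort()
            elif cluster.parent != parent:
                raise TaxonomyError(
                    f"cluster {label} at {rank} has conflicting parents "
                    f"{cluster.parent!r} vs {parent!r}")
            cluster.genomes.append(gid)
            cluster.genomes.sort()
            parent = label

    def detach_genome(self, gid: str) -> None:
        record = self.records.pop(gid)
        self.signatures.pop(gid)
        lineage = record.taxonomy
        for rank in reversed(RANKS):
            label = lineage[rank]
            cluster = self.clusters[rank][label]
            cluster.genomes.remove(gid)
            if not cluster.genomes:
                del self.clusters[rank][label]
                self.trees[rank].pop(label, None)
                if cluster.parent is not None:
                    parent_rank = RANKS[RANKS.index(rank) - 1]
                    self.clusters[parent_rank][cluster.parent].children.remove(label)

    # -- filters and trees ----------------------------------------------------

    def planned_size(self, rank: str, label: str) -> int:
        return self.manifest["plan"]["sizes"][rank][label]

    def set_planned_size(self, rank: str, label: str, size_bits: int) -> None:
        self.manifest["plan"]["sizes"][rank][label] = size_bits

    def _make_filter(self, sig: KmerSignature, size_bits: int) -> BloomFilter:
        return filter_from_signature(sig, size_bits, self.num_hashes, self.hash_seed)

    def build_cluster_tree(self, rank: str, label: str) -> SBTNode:
        """(Re)build the SBT of one cluster from its members or child roots."""
        cluster = self.clusters[rank][label]
        size = self.planned_size(rank, label)
        cluster.size_bits = size
        if rank == "species":
            leaves = [
                (gid, self._make_filter(self.signatures[gid], size))
                for gid in sorted(cluster.genomes)
            ]
        else:
            child_rank = RANKS[RANKS.index(rank) + 1]
            leaves = [
                (child, self._make_filter(self.union_signature_of(child_rank, child), size))
                for child in sorted(cluster.children)
            ]
        prefix = f"{rank[:2]}_"
        root = build_tree(leaves, id_prefix=prefix)
        ceiling = self.manifest["saturation_ceiling"]
        for node in root.walk():
            if node.filter.density() > ceiling:
                raise SaturationError(
                    f"filter of node {node.node_id} in {rank} tree {label!r} has "
                    f"density {node.filter.density():.3f} > ceiling {ceiling}")
        self.trees[rank][label] = root
        return root

    def build_all_trees(self) -> None:
        for rank in reversed(RANKS):
            for label in sorted(self.clusters[rank]):
                self.build_cluster_tree(rank, label)

    def refresh_centroids(self, clusters: Optional[Sequence[Cluster]] = None) -> None:
        if self.matrix is None:
            for rank in RANKS:
                for c in self.clusters[rank].values():
                    c.centroid_id = c.genomes[0] if c.genomes else None
            return
        targets = clusters if clusters is not None else [
            c for rank in RANKS for c in self.clusters[rank].values()]
        for c in targets:
            c.centroid_id = centroid(sorted(c.genomes), self.matrix)

    def refresh_matrix(self) -> None:
        gids = sorted(self.records)
        if len(gids) >= 2:
            self.matrix = pairwise_ani(gids, [self.signatures[g] for g in gids])
        else:
            self.matrix = None


def default_manifest(
    k: int,
    num_hashes: int = 1,
    hash_seed: int = 0,
    inflation: float = 1.0,
    min_occurrence: int = 1,
    expansion: float = 0.25,
    kingdom_floor: float = 0.01,
    saturation_ceiling: float = 0.95,
    dereplication_threshold: float = 99.0,
) -> dict:
    return {
        "format_version": DB_FORMAT_VERSION,
        "k": k,
        "num_hashes": num_hashes,
        "hash_seed": hash_seed,
        "inflation": inflation,
        "min_occurrence": min_occurrence,
        "expansion": expansion,
        "kingdom_floor": kingdom_floor,
        "saturation_ceiling": saturation_ceiling,
        "dereplication_threshold": dereplication_threshold,
        "canonical_kmers": True,
        "msbt_counter": 1,
        "genome_counter": 1,
        "rank_defaults": {r: list(v) for r, v in RANK_DEFAULT_BOUNDARIES.items()},
        "plan": {"sizes": {r: {} for r in RANKS}, "raw": {r: {} for r in RANKS}},
    }


def build_database(
    entries: Sequence[tuple[str, KmerSignature, Lineage]],
    manifest: dict,
    records: Optional[Sequence[GenomeRecord]] = None,
) -> TaxonomyDB:
    """Build a baseline database from fully classified reference genomes.

    ``entries`` are (genome_id, signature, full 7-rank lineage) triples.
    """
    if not entries:
        raise ValueError("cannot build a database from an empty genome list")
    db = TaxonomyDB(manifest=manifest)
    by_id = {r.genome_id: r for r in records} if records else {}
    for gid, sig, lineage in entries:
        if sig.k != db.k:
            raise ValueError(f"signature k={sig.k} does not match database k={db.k}")
        record = by_id.get(gid) or GenomeRecord(
            metasbt_id=db.allocate_genome_id(), genome_id=gid,
            genome_type="reference", taxonomy=lineage)
        record.taxonomy = lineage
        # baseline references vote with their ingest-time taxonomy later on
        if record.genome_type == "reference":
            record.extra.setdefault("original_lineage", lineage)
        db.attach_genome(record, sig)
    # sizing plan
    species_members = {
        label: [db.signatures[g] for g in sorted(c.genomes)]
        for label, c in sorted(db.clusters["species"].items())
    }
    parents = {
        rank: {label: c.parent for label, c in sorted(db.clusters[rank].items())}
        for rank in RANKS[1:]
    }
    plan = plan_bf_sizes(species_members, parents,
                         manifest["inflation"], manifest["min_occurrence"])
    manifest["plan"] = {"sizes": plan.sizes, "raw": plan.raw}
    db.refresh_matrix()
    compute_all_boundaries(db)
    db.refresh_centroids()
    db.build_all_trees()
    return db


def clusters_report(db: TaxonomyDB) -> pd.DataFrame:
    """Cluster summary: label, rank, knownness, composition, density, quality."""
    rows = []
    for rank in RANKS:
        for label in sorted(db.clusters[rank]):
            c = db.clusters[rank][label]
            refs = [g for g in c.genomes if db.records[g].genome_type == "reference"]
            mags = [g for g in c.genomes if db.records[g].genome_type == "MAG"]
            comp = [db.records[g].completeness for g in c.genomes
                    if db.records[g].completeness is not None]
            cont = [db.records[g].contamination for g in c.genomes
                    if db.records[g].contamination is not None]
            tree = db.trees[rank].get(label)
            rows.append({
                "label": label, "rank": rank,
                "known": "known" if c.is_known else "unknown",
                "n_references": len(refs), "n_MAGs": len(mags),
                "bf_density": (f"{tree.filter.density():.6f}" if tree else ""),
                "mean_completeness": (f"{sum(comp) / len(comp):.4f}" if comp else ""),
                "mean_contamination": (f"{sum(cont) / len(cont):.4f}" if cont else ""),
            })
    return pd.DataFrame(rows, columns=["label", "rank", "known", "n_references",
                                       "n_MAGs", "bf_density", "mean_completeness",
                                       "mean_contamination"])


# ---------------------------------------------------------------------------
# on-disk layout

def _slug(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", label)


def _save_signature(sig: KmerSignature, path: Path) -> None:
    header = _SIG_HEADER.pack(SIG_MAGIC, 1, sig.k, len(sig))
    path.write_bytes(header + sig.kmers.astype("<u8").tobytes())


def _load_signature(path: Path) -> KmerSignature:
    data = path.read_bytes()
    magic, version, k, count = _SIG_HEADER.unpack_from(data)
    if magic != SIG_MAGIC:
        raise FormatError(f"bad signature magic {magic!r}")
    if version != 1:
        raise FormatError(f"unsupported signature version {version}")
    kmers = np.frombuffer(data[_SIG_HEADER.size:], dtype="<u8").astype(np.uint64)
    if kmers.size != count:
        raise FormatError("signature length mismatch")
    return KmerSignature(k, kmers)


def save_db(db: TaxonomyDB, path: str | Path) -> Path:
    """Write the database directory; deterministic byte-for-byte."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "manifest.json").write_text(
        json.dumps(db.manifest, indent=2, sort_keys=True) + "\n")
    # genome registry (flattened records incl. lineage)
    rows = []
    for gid in sorted(db.records):
        r = db.records[gid]
        rows.append({
            "genome_id": gid,
            "metasbt_id": r.metasbt_id,
            "genome_type": r.genome_type,
            "lineage": r.taxonomy.serialize() if r.taxonomy else "",
            "sample_id": r.sample_id or "",
            "dataset_id": r.dataset_id or "",
            "completeness": "" if r.completeness is None else r.completeness,
            "contamination": "" if r.contamination is None else r.contamination,
            "strain_heterogeneity": ("" if r.strain_heterogeneity is None
                                     else r.strain_heterogeneity),
            "original_lineage": (
                r.extra["original_lineage"].serialize()
                if isinstance(r.extra.get("original_lineage"), Lineage)
                else r.extra.get("original_lineage", "") or ""),
        })
    pd.DataFrame(rows, columns=["genome_id", "metasbt_id", "genome_type", "lineage",
                                "sample_id", "dataset_id", "completeness",
                                "contamination", "strain_heterogeneity",
                                "original_lineage"]
                 ).to_csv(path / "genomes.tsv", sep="\t", index=False)
    # clusters
    crows = []
    for rank in RANKS:
        for label in sorted(db.clusters[rank]):
            c = db.clusters[rank][label]
            b = c.boundaries
            crows.append({
                "rank": rank, "label": label, "parent": c.parent or "",
                "children": ";".join(sorted(c.children)),
                "n_genomes": len(c.genomes),
                "centroid": c.centroid_id or "",
                "min_ani": "" if b is None else f"{b.min_ani:.17g}",
                "max_ani": "" if b is None else f"{b.max_ani:.17g}",
                "inferred": "" if b is None else str(b.inferred).lower(),
                "size_bits": c.size_bits,
            })
    pd.DataFrame(crows, columns=["rank", "label", "parent", "children", "n_genomes",
                                 "centroid", "min_ani", "max_ani", "inferred",
                                 "size_bits"]).to_csv(
        path / "clusters.tsv", sep="\t", index=False)
    if db.matrix is not None:
        db.matrix.to_tsv(path / "ani.tsv")
    sig_dir = path / "signatures"
    sig_dir.mkdir(exist_ok=True)
    for gid in sorted(db.signatures):
        _save_signature(db.signatures[gid], sig_dir / f"{_slug(gid)}.kms")
    tree_dir = path / "trees"
    for rank in RANKS:
        for label in sorted(db.trees[rank]):
            save_tree(db.trees[rank][label], tree_dir, f"{rank}__{_slug(label)}")
    return path


def load_db(path: str | Path) -> TaxonomyDB:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest.get("format_version") != DB_FORMAT_VERSION:
        raise FormatError(
            f"unsupported database format version {manifest.get('format_version')!r}")
    db = TaxonomyDB(manifest=manifest)
    genomes = pd.read_csv(path / "genomes.tsv", sep="\t", dtype=str).fillna("")
    clusters = pd.read_csv(path / "clusters.tsv", sep="\t", dtype=str).fillna("")
    for row in genomes.itertuples():
        record = GenomeRecord(
            metasbt_id=row.metasbt_id, genome_id=row.genome_id,
            genome_type=row.genome_type,
            taxonomy=parse_lineage(row.lineage) if row.lineage else None,
            sample_id=row.sample_id or None, dataset_id=row.dataset_id or None,
            completeness=float(row.completeness) if row.completeness else None,
            contamination=float(row.contamination) if row.contamination else None,
            strain_heterogeneity=(float(row.strain_heterogeneity)
                                  if row.strain_heterogeneity else None),
        )
        if getattr(row, "original_lineage", ""):
            record.extra["original_lineage"] = parse_lineage(row.original_lineage)
        db.records[row.genome_id] = record
        db.signatures[row.genome_id] = _load_signature(
            path / "signatures" / f"{_slug(row.genome_id)}.kms")
    for row in clusters.itertuples():
        c = Cluster(
            label=row.label, rank=row.rank, parent=row.parent or None,
            children=row.children.split(";") if row.children else [],
        )
        c.centroid_id = row.centroid or None
        c.size_bits = int(row.size_bits)
        if row.min_ani:
            c.boundaries = Boundaries(float(row.min_ani), float(row.max_ani),
                                      row.inferred == "true")
        db.clusters[row.rank][row.label] = c
    # genome membership per cluster from lineages
    for gid, record in db.records.items():
        for rank in RANKS:
            label = record.taxonomy[rank]
            db.clusters[rank][label].genomes.append(gid)
    for rank in RANKS:
        for c in db.clusters[rank].values():
            c.genomes.sort()
    if (path / "ani.tsv").exists():
        db.matrix = PairwiseMatrix.from_tsv(path / "ani.tsv")
    tree_dir = path / "trees"
    for rank in RANKS:
        for label in sorted(db.clusters[rank]):
            name = f"{rank}__{_slug(label)}"
            if (tree_dir / f"{name}.json").exists():
                db.trees[rank][label] = load_tree(tree_dir, name)
    return db
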