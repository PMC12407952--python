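"""Taxonomy-dump and library export for external k-mer classifiers.

Every cluster — known and unknown (``MSBT`` labels verbatim) — becomes a
node of an NCBI-style taxonomy dump (``nodes.dmp``/``names.dmp``,
tab-pipe-tab separated) rooted at a synthetic ``root`` node that is its
own parent, with taxids assigned by deterministic depth-first numbering.
A ``seqid2taxid.map`` ties every genome id to its species taxid, and when
sequences are supplied a library FASTA is emitted with
``kraken:taxid``-style headers, which is everything a k-mer classifier
needs to build a custom database over the forest, unknown taxa included.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from .database import TaxonomyDB
from .kmers import RANKS

ROOT_TAXID = 1


def _dfs_order(db: TaxonomyDB) -> list[tuple[str, str]]:
    """(rank, label) pairs in deterministic depth-first order."""
    order: list[tuple[str, str]] = []

    def visit(rank: str, label: str) -> None:
        order.append((rank, label))
        if rank != "species":
            child_rank = RANKS[RANKS.index(rank) + 1]
            for child in sorted(db.clusters[rank][label].children):
                visit(child_rank, child)

    for kingdom in sorted(db.clusters["kingdom"]):
        visit("kingdom", kingdom)
    return order


def export_classifier_inputs(
    db: TaxonomyDB,
    out_dir: str | Path,
    sequences: Optional[dict[str, str]] = None,
) -> dict[str, Path]:
    """Write nodes.dmp, names.dmp, seqid2taxid.map and (optionally) library.fna."""
    out_dir = Path(out_dir)
    (out_dir / "taxonomy").mkdir(parents=True, exist_ok=True)
    order = _dfs_order(db)
    taxids = {("root", "root"): ROOT_TAXID}
    for i, key in enumerate(order, start=ROOT_TAXID + 1):
        taxids[key] = i

    nodes_lines = [f"{ROOT_TAXID}\t|\t{ROOT_TAXID}\t|\tno rank\t|\n"]
    names_lines = [f"{ROOT_TAXID}\t|\troot\t|\t\t|\tscientific name\t|\n"]
    for rank, label in order:
        cluster = db.clusters[rank][label]
        if rank == "kingdom":
            parent_id = ROOT_TAXID
        else:
            parent_rank = RANKS[RANKS.index(rank) - 1]
            parent_id = taxids[(parent_rank, cluster.parent)]
        taxid = taxids[(rank, label)]
        nodes_lines.append(f"{taxid}\t|\t{parent_id}\t|\t{rank}\t|\n")
        names_lines.append(f"{taxid}\t|\t{label}\t|\t\t|\tscientific name\t|\n")
    nodes_path = out_dir / "taxonomy" / "nodes.dmp"
    names_path = out_dir / "taxonomy" / "names.dmp"
    nodes_path.write_text("".join(nodes_lines))
    names_path.write_text("".join(names_lines))

    map_lines = []
    for gid in sorted(db.records):
        species = db.records[gid].taxonomy["species"]
        map_lines.append(f"{gid}\t{taxids[('species', species)]}\n")
    map_path = out_dir / "seqid2taxid.map"
    map_path.write_text("".join(map_lines))

    out = {"nodes": nodes_path, "names": names_path, "seqid2taxid": map_path}
    if sequences is not None:
        lib_path = out_dir / "library.fna"
        with open(lib_path, "w") as fh:
            for gid in sorted(sequences):
                species = db.records[gid].taxonomy["species"]
                taxid = taxids[("species", species)]
                fh.write(f">{gid}|kraken:taxid|{taxid}\n{sequences[gid]}\n")
        out["library"] = lib_path
    return out


def parse_taxonomy_dump(
    nodes_path: str | Path, names_path: str | Path
) -> dict[tuple[str, str], Optional[tuple[str, str]]]:
    """Parse a dump back into a rank forest: (rank, label) -> parent or None.

    The synthetic root node is dropped; kingdom nodes map to None.
    """
    def fields(line: str) -> list[str]:
        return [f.strip() for f in line.rstrip("\n").rstrip("|").split("\t|\t")]

    parents: dict[int, int] = {}
    ranks: dict[int, str] = {}
    for line in Path(nodes_path).read_text().splitlines():
        taxid, parent, rank = fields(line + "\n")[:3]
        parents[int(taxid)] = int(parent)
        ranks[int(taxid)] = rank
    names: dict[int, str] = {}
    for line in Path(names_path).read_text().splitlines():
        parts = fields(line + "\n")
        if parts[3] == "scientific name":
            names[int(parts[0])] = parts[1]
    forest: dict[tuple[str, str], Optional[tuple[str, str]]] = {}
    for taxid, parent in parents.items():
        if taxid == parent:  # synthetic root
            continue
        key = (ranks[taxid], names[taxid])
        if ranks.get(parent) == "no rank":
            forest[key] = None
        else:
            forest[key] = (ranks[parent], names[parent])
    return forest
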