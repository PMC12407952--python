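"""Sequence Bloom Trees: build, query, audit, serialize.

A tree node holds one Bloom filter; an internal node's filter is the
bitwise OR of its children, so the root covers every k-mer of every leaf.
Leaves of a species tree are genome filters; leaves of a genus tree are
species roots (re-populated at the genus filter size from the species'
retained exact k-mer union), and so on to the single kingdom tree.

Topology is built by greedy agglomeration — repeatedly joining the two
nodes whose filters have the highest (bit-level) Jaccard — which only
affects traversal speed, never query results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

from .bloom import BloomFilter, ShapeError
from .kmers import KmerSignature


@dataclass
class SBTNode:
    node_id: str
    filter: BloomFilter
    children: list["SBTNode"] = field(default_factory=list)
    payload: str | None = None  # genome id (species leaves) / child cluster label

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["SBTNode"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def leaves(self) -> Iterator["SBTNode"]:
        for node in self.walk():
            if node.is_leaf:
                yield node


def build_tree(leaves: Sequence[tuple[str, BloomFilter]], id_prefix: str = "n") -> SBTNode:
    """Agglomerate leaf filters into a binary-ish SBT.

    Pairs the two current nodes with the highest filter Jaccard first
    (ties: lowest index pair), making similar genomes share deep subtrees.
    Internal filters are unions of their children; node ids are assigned
    deterministically after the topology is fixed.
    """
    if not leaves:
        raise ValueError("cannot build a tree with no leaves")
    for _, bf in leaves[1:]:
        leaves[0][1]._compatible(bf)
    nodes: list[SBTNode] = [
        SBTNode(node_id="", filter=bf.copy(), payload=payload)
        for payload, bf in leaves
    ]
    while len(nodes) > 1:
        best = None
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                inter = nodes[i].filter.intersection_popcount(nodes[j].filter)
                union = nodes[i].filter.union_popcount(nodes[j].filter)
                sim = inter / union if union else 1.0
                if best is None or sim > best[0]:
                    best = (sim, i, j)
        _, i, j = best
        parent = SBTNode(
            node_id="",
            filter=nodes[i].filter.union(nodes[j].filter),
            children=[nodes[i], nodes[j]],
        )
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [parent]
    root = nodes[0]
    for idx, node in enumerate(root.walk()):
        node.node_id = f"{id_prefix}{idx:04d}"
    return root


def query_tree(
    root: SBTNode, query: KmerSignature, min_fraction: float
) -> list[tuple[str, int]]:
    """Pruned SBT traversal reporting (leaf payload, matched k-mer count).

    At each node the query k-mers are probed against the node filter;
    subtrees where fewer than ``min_fraction·|query|`` k-mers match are
    pruned.  Because internal filters contain their leaves' bits, pruning
    never loses a leaf that would itself pass the threshold (counts are
    monotone down the tree).  Results sort by count descending, ties by
    payload id.
    """
    if len(query) == 0:
        raise ValueError("empty query")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    threshold = min_fraction * len(query)
    hits: list[tuple[str, int]] = []

    def visit(node: SBTNode) -> None:
        count = node.filter.count_hits(query)
        if count < threshold:
            return
        if node.is_leaf:
            hits.append((node.payload or node.node_id, count))
        else:
            for child in node.children:
                visit(child)

    visit(root)
    return sorted(hits, key=lambda t: (-t[1], t[0]))


def audit_union_property(root: SBTNode) -> list[str]:
    """Node ids of internal nodes whose filter fails to cover its children."""
    bad = []
    for node in root.walk():
        for child in node.children:
            if not node.filter.contains_bits(child.filter):
                bad.append(node.node_id)
                break
    return bad


def stack_level(
    child_signatures: dict[str, KmerSignature],
    grouping: dict[str, str],
    parent_sizes: dict[str, int],
    num_hashes: int = 1,
    hash_seed: int = 0,
) -> dict[str, SBTNode]:
    """Stack one taxonomic level: child cluster roots become parent leaves.

    Children are re-populated into the parent's (larger) filter size from
    their retained exact k-mer unions — filters of different lengths are
    not bit-compatible, so the exact signature is the carrier between
    levels — and agglomerated per parent exactly as in tree building.
    Raises on a child whose label is missing from ``grouping``.
    """
    from .bloom import filter_from_signature  # local: avoid cycle at import
    by_parent: dict[str, list[tuple[str, KmerSignature]]] = {}
    for child, sig in sorted(child_signatures.items()):
        if child not in grouping:
            raise KeyError(f"orphan child label {child!r}: not in grouping")
        by_parent.setdefault(grouping[child], []).append((child, sig))
    out: dict[str, SBTNode] = {}
    for parent, children in sorted(by_parent.items()):
        size = parent_sizes[parent]
        leaves = [(label, filter_from_signature(sig, size, num_hashes, hash_seed))
                  for label, sig in children]
        out[parent] = build_tree(leaves, id_prefix=f"{parent}_")
    return out


# ---------------------------------------------------------------------------
# serialization: one JSON topology per tree + one .bf file per node

def save_tree(root: SBTNode, directory: Path, name: str) -> None:
    directory.mkdir(parents=True, exist_ok=True)

    def encode(node: SBTNode) -> dict:
        return {
            "node_id": node.node_id,
            "payload": node.payload,
            "children": [encode(c) for c in node.children],
        }

    (directory / f"{name}.json").write_text(
        json.dumps(encode(root), indent=0, sort_keys=True))
    for node in root.walk():
        node.filter.save(directory / f"{name}.{node.node_id}.bf")


def load_tree(directory: Path, name: str) -> SBTNode:
    spec = json.loads((directory / f"{name}.json").read_text())

    def decode(doc: dict) -> SBTNode:
        bf = BloomFilter.load(directory / f"{name}.{doc['node_id']}.bf")
        return SBTNode(
            node_id=doc["node_id"],
            filter=bf,
            children=[decode(c) for c in doc["children"]],
            payload=doc["payload"],
        )

    return decode(spec)
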