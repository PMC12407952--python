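"""Canonical k-mer extraction and Bloom-filter size planning.

Genomes are reduced to sets of canonical k-mers (the lexicographically
smaller of each k-mer and its reverse complement) encoded as 2-bit-per-base
integers, so a signature is a sorted ``uint64`` array.  Distinct-k-mer
counts over genome collections drive the per-cluster Bloom-filter sizing:
a species filter is sized to the number of distinct k-mers of its genomes,
a genus filter to the distinct count of the union of its species, and so on
to the kingdom, each inflated by a headroom fraction so the database can
absorb future genomes without saturating.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i

MAX_K = 31  # 2 bits/base in a uint64, one spare pair


@dataclass(frozen=True)
class KmerSignature:
    """Set of canonical k-mers of one genome (or a union of genomes)."""

    k: int
    kmers: np.ndarray  # sorted unique uint64

    def __post_init__(self) -> None:
        if not 1 <= self.k <= MAX_K:
            raise ValueError(f"k must be in [1, {MAX_K}], got {self.k}")

    def __len__(self) -> int:
        return int(self.kmers.size)

    def union(self, other: "KmerSignature") -> "KmerSignature":
        _check_same_k([self, other])
        return KmerSignature(self.k, np.union1d(self.kmers, other.kmers))


def _check_same_k(signatures: Sequence[KmerSignature]) -> int:
    ks = {s.k for s in signatures}
    if len(ks) > 1:
        raise ValueError(f"mixed k-mer lengths: {sorted(ks)}")
    return ks.pop() if ks else 0


def encode_kmers(windows: np.ndarray, k: int) -> np.ndarray:
    """Pack an (n, k) array of 2-bit base codes into canonical uint64 ints.

    MSB-first packing preserves lexicographic order (A<C<G<T), so the
    integer minimum of a k-mer and its reverse complement is exactly the
    canonical (lexicographically smaller) form.
    """
    weights = (np.uint64(1) << (np.uint64(2) * np.arange(k - 1, -1, -1, dtype=np.uint64)))
    fwd = windows.astype(np.uint64) @ weights
    rc = (np.uint64(3) - windows[:, ::-1].astype(np.uint64)) @ weights
    return np.minimum(fwd, rc)


def extract_kmers(sequences: Iterable[str], k: int) -> KmerSignature:
    """Canonical k-mer signature of a set of nucleotide strings.

    Windows containing any non-ACGT character (IUPAC ambiguity codes, N)
    are skipped.  Sequences shorter than ``k`` contribute nothing.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    parts: list[np.ndarray] = []
    for seq in sequences:
        codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        if codes.size < k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = ~(windows == 255).any(axis=1)
        if valid.any():
            parts.append(encode_kmers(windows[valid], k))
    if not parts:
        return KmerSignature(k, np.empty(0, dtype=np.uint64))
    return KmerSignature(k, np.unique(np.concatenate(parts)))


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTacgt", "TGCAtgca")
    return seq.translate(comp)[::-1]


def read_fasta(path: str | Path) -> list[str]:
    """All sequences of a FASTA or gzip-compressed FASTA file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        return [str(rec.seq) for rec in SeqIO.parse(handle, "fasta")]


def signature_from_fasta(path: str | Path, k: int) -> KmerSignature:
    return extract_kmers(read_fasta(path), k)


def count_distinct(signatures: Sequence[KmerSignature], min_occurrence: int = 1) -> int:
    """Number of k-mers occurring in at least ``min_occurrence`` genomes.

    Occurrence is counted across the multiset of per-genome k-mer sets
    (a k-mer repeated inside one genome still counts once for that genome).
    """
    if min_occurrence < 1:
        raise ValueError("min_occurrence must be >= 1")
    signatures = [s for s in signatures if len(s)]
    if not signatures:
        return 0
    _check_same_k(signatures)
    pooled = np.concatenate([s.kmers for s in signatures])
    if min_occurrence == 1:
        return int(np.unique(pooled).size)
    _, counts = np.unique(pooled, return_counts=True)
    return int((counts >= min_occurrence).sum())


def union_signature(signatures: Sequence[KmerSignature]) -> KmerSignature:
    k = _check_same_k(list(signatures))
    if not signatures:
        raise ValueError("empty signature list")
    return KmerSignature(k, np.unique(np.concatenate([s.kmers for s in signatures])))


def _round_up64(bits: int) -> int:
    return max(64, ((bits + 63) // 64) * 64)


@dataclass
class BfSizingPlan:
    """Per-cluster Bloom-filter sizes, grouped by rank.

    ``sizes[rank][label]`` is the planned bit length for that cluster's
    filters.  Raw distinct-k-mer estimates are inflated by ``(1+inflation)``
    (default: 100% headroom against saturation under future updates) and
    rounded up to a multiple of 64 bits.
    """

    inflation: float = 1.0
    min_occurrence: int = 1
    sizes: dict[str, dict[str, int]] = field(default_factory=dict)
    raw: dict[str, dict[str, int]] = field(default_factory=dict)  # pre-inflation counts

    def size_of(self, rank: str, label: str) -> int:
        return self.sizes[rank][label]


def plan_bf_sizes(
    species_members: Mapping[str, Sequence[KmerSignature]],
    parents: Mapping[str, Mapping[str, str]],
    inflation: float = 1.0,
    min_occurrence: int = 1,
) -> BfSizingPlan:
    """Plan filter sizes for every cluster at every rank.

    Parameters
    ----------
    species_members:
        species label -> signatures of the genomes attached to it.
    parents:
        per child rank, map child label -> parent label; keys are the child
        ranks ``phylum``..``species`` (i.e. ``parents["species"]`` maps each
        species to its genus).
    inflation:
        headroom fraction added to every raw distinct-k-mer estimate.
    """
    if inflation < 0:
        raise ValueError("inflation must be >= 0")
    plan = BfSizingPlan(inflation=inflation, min_occurrence=min_occurrence)
    # species level: exact distinct count of the member genomes
    groups: dict[str, list[KmerSignature]] = {
        label: list(sigs) for label, sigs in species_members.items()
    }
    raw: dict[str, dict[str, int]] = {}
    for rank in reversed(RANKS):
        raw[rank] = {
            label: count_distinct(sigs, min_occurrence) for label, sigs in groups.items()
        }
        if rank == "kingdom":
            break
        mapping = parents[rank]
        parent_groups: dict[str, list[KmerSignature]] = {}
        for label, sigs in groups.items():
            parent_groups.setdefault(mapping[label], []).extend(sigs)
        groups = parent_groups
    for rank in RANKS:
        plan.raw[rank] = dict(sorted(raw[rank].items()))
        plan.sizes[rank] = {
            label: _round_up64(int(np.ceil(n * (1.0 + inflation))))
            for label, n in plan.raw[rank].items()
        }
    return plan
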