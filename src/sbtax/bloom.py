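"""Bloom filters over canonical k-mers.

A filter is an ``m``-bit vector (stored as little-endian uint64 words) with
``h`` seeded hash functions.  Hashing is a vectorised splitmix64 finaliser:
position_i = splitmix64(kmer XOR stream_i) mod m, where stream_i is the
i-th value of a splitmix64 sequence started at the filter seed.  With a
single hash (the default) a union of filters is exactly the filter of the
union of the inserted sets, which is what makes Sequence Bloom Tree nodes
well-defined.

Serialization: fixed header (magic ``TSBT``, format version, m, h, seed, k)
followed by the bit vector as little-endian bytes, LSB-first within each
byte; bit ``i`` lives in byte ``i // 8`` at bit ``i % 8``.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kmers import KmerSignature

MAGIC = b"TSBT"
FORMAT_VERSION = 1
_HEADER = struct.Struct("<4sHHQHqQ")  # magic, version, reserved, m, h, seed, k

_C1 = np.uint64(0x9E3779B97F4A7C15)
_C2 = np.uint64(0xBF58476D1CE4E5B9)
_C3 = np.uint64(0x94D049BB133111EB)


def _splitmix64(x: np.ndarray | np.uint64) -> np.ndarray | np.uint64:
    z = (x + _C1).astype(np.uint64) if isinstance(x, np.ndarray) else np.uint64(x + _C1)
    z = (z ^ (z >> np.uint64(30))) * _C2
    z = (z ^ (z >> np.uint64(27))) * _C3
    return z ^ (z >> np.uint64(31))


class ShapeError(ValueError):
    """Raised when filters with incompatible parameters are combined."""


class FormatError(ValueError):
    """Raised on malformed serialized filters."""


@dataclass
class BloomFilter:
    size_bits: int
    num_hashes: int = 1
    hash_seed: int = 0
    k: int = 0  # k-mer length the filter was built for (0 = untyped)
    words: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.size_bits < 1:
            raise ValueError("size_bits must be positive")
        if self.num_hashes < 1:
            raise ValueError("num_hashes must be positive")
        n_words = (self.size_bits + 63) // 64
        if self.words is None:
            self.words = np.zeros(n_words, dtype=np.uint64)
        elif self.words.size != n_words:
            raise ShapeError("word array does not match size_bits")

    # -- hashing ---------------------------------------------------------

    def _streams(self) -> np.ndarray:
        base = np.uint64(self.hash_seed % (1 << 64))
        return _splitmix64(base + np.arange(self.num_hashes, dtype=np.uint64))

    def _positions(self, elements: np.ndarray) -> np.ndarray:
        """(h, n) array of bit positions for each element."""
        elements = np.asarray(elements, dtype=np.uint64)
        with np.errstate(over="ignore"):
            hashed = _splitmix64(elements[None, :] ^ self._streams()[:, None])
        return hashed % np.uint64(self.size_bits)

    # -- mutation / queries ----------------------------------------------

    def add(self, elements: np.ndarray | KmerSignature) -> "BloomFilter":
        if isinstance(elements, KmerSignature):
            elements = elements.kmers
        if np.asarray(elements).size == 0:
            return self
        pos = self._positions(elements).ravel()
        np.bitwise_or.at(self.words, pos >> np.uint64(6),
                         np.uint64(1) << (pos & np.uint64(63)))
        return self

    def _hits(self, elements: np.ndarray) -> np.ndarray:
        """Boolean membership vector (all h bits set) for each element."""
        pos = self._positions(np.asarray(elements, dtype=np.uint64))
        bits = (self.words[pos >> np.uint64(6)] >> (pos & np.uint64(63))) & np.uint64(1)
        return bits.all(axis=0)

    def lookup(self, element: int) -> bool:
        return bool(self._hits(np.array([element], dtype=np.uint64))[0])

    def count_hits(self, elements: np.ndarray | KmerSignature) -> int:
        """Number of query elements reported present (no false negatives)."""
        if isinstance(elements, KmerSignature):
            elements = elements.kmers
        if np.asarray(elements).size == 0:
            return 0
        return int(self._hits(elements).sum())

    def popcount(self) -> int:
        return int(np.bitwise_count(self.words).sum())

    def density(self) -> float:
        return self.popcount() / self.size_bits

    # -- algebra ----------------------------------------------------------

    def _compatible(self, other: "BloomFilter") -> None:
        if (self.size_bits, self.num_hashes, self.hash_seed) != (
            other.size_bits, other.num_hashes, other.hash_seed
        ):
            raise ShapeError(
                "incompatible filters: "
                f"({self.size_bits},{self.num_hashes},{self.hash_seed}) vs "
                f"({other.size_bits},{other.num_hashes},{other.hash_seed})"
            )

    def union(self, other: "BloomFilter") -> "BloomFilter":
        self._compatible(other)
        return BloomFilter(self.size_bits, self.num_hashes, self.hash_seed,
                           max(self.k, other.k), self.words | other.words)

    def intersection_popcount(self, other: "BloomFilter") -> int:
        self._compatible(other)
        return int(np.bitwise_count(self.words & other.words).sum())

    def union_popcount(self, other: "BloomFilter") -> int:
        self._compatible(other)
        return int(np.bitwise_count(self.words | other.words).sum())

    def contains_bits(self, other: "BloomFilter") -> bool:
        """True iff this filter's bit set is a superset of other's."""
        self._compatible(other)
        return bool(((self.words | other.words) == self.words).all())

    def copy(self) -> "BloomFilter":
        return BloomFilter(self.size_bits, self.num_hashes, self.hash_seed,
                           self.k, self.words.copy())

    # -- serialization -----------------------------------------------------

    def to_bytes(self) -> bytes:
        header = _HEADER.pack(MAGIC, FORMAT_VERSION, 0, self.size_bits,
                              self.num_hashes, self.hash_seed, self.k)
        return header + self.words.astype("<u8").tobytes()

    @classmethod
    def from_bytes(cls, data: bytes) -> "BloomFilter":
        if len(data) < _HEADER.size:
            raise FormatError("truncated filter header")
        magic, version, _, m, h, seed, k = _HEADER.unpack_from(data)
        if magic != MAGIC:
            raise FormatError(f"bad magic {magic!r}, expected {MAGIC!r}")
        if version != FORMAT_VERSION:
            raise FormatError(f"unsupported filter format version {version}")
        n_words = (m + 63) // 64
        body = data[_HEADER.size:]
        if len(body) != 8 * n_words:
            raise FormatError("filter body length mismatch")
        words = np.frombuffer(body, dtype="<u8").astype(np.uint64)
        return cls(m, h, seed, k, words)

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(self.to_bytes())

    @classmethod
    def load(cls, path: str | Path) -> "BloomFilter":
        return cls.from_bytes(Path(path).read_bytes())


def filter_from_signature(
    sig: KmerSignature, size_bits: int, num_hashes: int = 1, hash_seed: int = 0
) -> BloomFilter:
    bf = BloomFilter(size_bits, num_hashes, hash_seed, k=sig.k)
    bf.add(sig)
    return bf
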