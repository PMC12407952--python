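"""Independent brute-force oracles shared by acceptance-level tests."""

from __future__ import annotations

import itertools
from typing import Iterator, Sequence


def set_partitions(items: Sequence) -> Iterator[list[list]]:
    """All set partitions of ``items`` (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1:]
        yield [[first]] + partition


def unique_threshold_partition(matrix, cut: float):
    """The unique partition with within-pairs ≥ cut and cross-pairs < cut.

    Returns None when no partition, or more than one, satisfies both
    conditions (the instance is then not well-separated).
    """
    found = None
    for partition in set_partitions(matrix.ids):
        ok = True
        for block in partition:
            for a, b in itertools.combinations(block, 2):
                if matrix.ani_of(a, b) < cut:
                    ok = False
        if ok:
            for b1, b2 in itertools.combinations(partition, 2):
                for a in b1:
                    for b in b2:
                        if matrix.ani_of(a, b) >= cut:
                            ok = False
        if ok:
            canon = frozenset(frozenset(b) for b in partition)
            if found is not None and canon != found:
                return None
            found = canon
    return found
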