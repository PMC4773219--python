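"""Independent brute-force oracles used to check the interval primitives.

Everything here deliberately avoids the package's own overlap/clustering
code paths: overlaps are counted base by base over explicit coordinate
sets, and single-linkage clusters are found by enumerating *all* set
partitions and selecting the finest one in which every linked pair shares
a block.
"""
from __future__ import annotations

from fractions import Fraction


def overlap_bases(a, b) -> int:
    """Base-by-base intersection count via explicit coordinate sets."""
    if a.chromosome != b.chromosome:
        return 0
    return len(set(range(a.start, a.end)) & set(range(b.start, b.end)))


def overlap_fractions(a, b) -> tuple[Fraction, Fraction]:
    ov = overlap_bases(a, b)
    return Fraction(ov, a.length), Fraction(ov, b.length)


def linked_oracle(a, b, fraction) -> bool:
    fa, fb = overlap_fractions(a, b)
    ov = overlap_bases(a, b)
    return ov > 0 and min(fa, fb) >= Fraction(fraction).limit_denominator(10**6)


def set_partitions(items: list) -> list[list[list]]:
    """All set partitions of ``items`` (Bell-number many)."""
    if not items:
        return [[]]
    first, rest = items[0], items[1:]
    out = []
    for p in set_partitions(rest):
        for i in range(len(p)):
            out.append(p[:i] + [p[i] + [first]] + p[i + 1 :])
        out.append(p + [[first]])
    return out


def single_linkage_oracle(intervals, fraction) -> list[frozenset[int]]:
    """Single-linkage clusters of interval indices by exhaustive enumeration.

    Among all partitions in which every linked pair of items shares a
    block, the finest one (most blocks) is the connected-component
    partition of the linkage graph.
    """
    idx = list(range(len(intervals)))
    links = [
        (i, j)
        for i in idx
        for j in idx
        if i < j and linked_oracle(intervals[i], intervals[j], fraction)
    ]
    best = None
    for p in set_partitions(idx):
        block_of = {}
        for bi, block in enumerate(p):
            for item in block:
                block_of[item] = bi
        if all(block_of[i] == block_of[j] for i, j in links):
            if best is None or len(p) > len(best):
                best = p
    assert best is not None
    return sorted(
        (frozenset(b) for b in best), key=lambda s: tuple(sorted(s))
    )
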