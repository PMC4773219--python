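"""Interval arithmetic primitives: reciprocal overlap and single-linkage
clustering of overlapping intervals.

These are the core primitives behind cross-algorithm consensus merging, the
novelty rule against reference sets, singleton detection and recurrence
clustering, so they are implemented here once and cross-checked against
brute-force oracles in the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence, TypeVar

from .model import GenomicInterval, chromosome_rank

T = TypeVar("T")


@dataclass(frozen=True)
class OverlapResult:
    """Intersection length and the fraction of each interval it covers."""

    overlap_bp: int
    fraction_a: float
    fraction_b: float

    @property
    def reciprocal_fraction(self) -> float:
        return min(self.fraction_a, self.fraction_b)


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> OverlapResult:
    """Overlap of two intervals, as bp and as a fraction of each length.

    Intervals on different chromosomes overlap by zero. Two intervals have
    reciprocal overlap >= f when the intersection covers at least fraction f
    of *each* of them.
    """
    if a.chromosome != b.chromosome:
        return OverlapResult(0, 0.0, 0.0)
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return OverlapResult(0, 0.0, 0.0)
    return OverlapResult(ov, ov / a.length, ov / b.length)


def is_linked(a: GenomicInterval, b: GenomicInterval, fraction: float) -> bool:
    """True when a and b overlap reciprocally at >= ``fraction``.

    A positive intersection is always required, so disjoint intervals are
    never linked even at fraction 0.
    """
    r = reciprocal_overlap(a, b)
    return r.overlap_bp > 0 and r.reciprocal_fraction >= fraction


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def single_linkage_clusters(
    items: Sequence[T],
    get_interval: Callable[[T], GenomicInterval],
    fraction: float,
) -> list[list[T]]:
    """Single-linkage clusters under the reciprocal-overlap linkage.

    Two items are linked when their intervals overlap reciprocally at
    >= ``fraction``; clusters are the connected components of the linkage
    graph. Items on different chromosomes never cluster together. Output
    clusters and their members are ordered by (chromosome, start, end).
    """
    n = len(items)
    order = sorted(
        range(n),
        key=lambda i: (
            chromosome_rank(get_interval(items[i]).chromosome),
            get_interval(items[i]).start,
            get_interval(items[i]).end,
        ),
    )
    uf = _UnionFind(n)
    for ai in range(n):
        i = order[ai]
        iv_i = get_interval(items[i])
        for aj in range(ai + 1, n):
            j = order[aj]
            iv_j = get_interval(items[j])
            if iv_j.chromosome != iv_i.chromosome or iv_j.start >= iv_i.end:
                break  # sorted by start: no further interval overlaps iv_i
            if is_linked(iv_i, iv_j, fraction):
                uf.union(i, j)
    clusters: dict[int, list[int]] = {}
    for ai in order:
        clusters.setdefault(uf.find(ai), []).append(ai)
    out = [[items[i] for i in members] for members in clusters.values()]
    out.sort(key=lambda c: get_interval(c[0]).sort_key())
    return out


def outer_bounds(intervals: Sequence[GenomicInterval]) -> GenomicInterval:
    """Smallest interval covering all inputs (which must share a chromosome)."""
    chroms = {iv.chromosome for iv in intervals}
    if len(chroms) != 1:
        raise ValueError("cannot take outer bounds across chromosomes")
    return GenomicInterval(
        chroms.pop(),
        min(iv.start for iv in intervals),
        max(iv.end for iv in intervals),
    )
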