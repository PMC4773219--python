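"""Core data model shared across the pipeline.

Coordinates are 0-based half-open *everywhere inside the package*; the I/O
layer converts to and from the on-disk conventions of each dialect
(1-based inclusive for rawcnv/DGV-style tables, half-open for BED-flavoured
files). Chromosome labels are normalized to the canonical ``chr1``..``chrY``
set on construction.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

CANONICAL_CHROMOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23)) + (
    "chrX",
    "chrY",
)
_CHROM_SET = frozenset(CANONICAL_CHROMOSOMES)
_CHROM_RANK = {c: i for i, c in enumerate(CANONICAL_CHROMOSOMES)}
SEX_CHROMOSOMES = frozenset({"chrX", "chrY"})
AUTOSOMES: tuple[str, ...] = CANONICAL_CHROMOSOMES[:22]


def normalize_chromosome(label: object) -> str:
    """Map ``1``, ``chr1``, ``X``, ``chrx`` ... onto the canonical label set.

    Raises ``ValueError`` for labels outside ``chr1``..``chr22``, ``chrX``,
    ``chrY``.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.lower() in ("x", "y"):
        s = s.upper()
    name = f"chr{s}"
    if name not in _CHROM_SET:
        raise ValueError(f"unknown chromosome label: {label!r}")
    return name


def chromosome_rank(chromosome: str) -> int:
    """Sort key giving the conventional chr1..chr22, chrX, chrY order."""
    return _CHROM_RANK[chromosome]


class CnvType(str, Enum):
    GAIN = "gain"
    LOSS = "loss"

    @classmethod
    def parse(cls, label: object) -> "CnvType":
        s = str(label).strip().lower()
        if s in ("gain", "dup", "duplication", "amp"):
            return cls.GAIN
        if s in ("loss", "del", "deletion"):
            return cls.LOSS
        raise ValueError(f"unknown CNV type label: {label!r}")

    @classmethod
    def from_copy_number(cls, copy_number: int) -> "CnvType":
        if copy_number < 2:
            return cls.LOSS
        if copy_number > 2:
            return cls.GAIN
        raise ValueError("copy number 2 is diploid, not a CNV")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a canonical chromosome."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty interval: {self.chromosome}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.start
            and other.end <= self.end
        )

    def sort_key(self) -> tuple[int, int, int]:
        return (chromosome_rank(self.chromosome), self.start, self.end)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chromosome}:{self.start}-{self.end}"


@dataclass(frozen=True)
class CnvCall:
    """A single CNV call from one algorithm in one sample."""

    sample_id: str
    interval: GenomicInterval
    cnv_type: CnvType
    copy_number: Optional[int] = None
    probe_count: int = 0
    algorithm: str = ""
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if self.copy_number is not None:
            if self.copy_number < 0:
                raise ValueError(f"negative copy number: {self.copy_number}")
            implied = CnvType.from_copy_number(self.copy_number)
            if implied is not self.cnv_type:
                raise ValueError(
                    f"copy number {self.copy_number} inconsistent with "
                    f"type {self.cnv_type.value}"
                )
        if self.probe_count < 0:
            raise ValueError("probe_count must be >= 0")

    def sort_key(self) -> tuple:
        return (*self.interval.sort_key(), self.sample_id, self.algorithm)


@dataclass(frozen=True)
class ConsensusCnv:
    """A merged call supported by one or more algorithms in one sample.

    ``interval`` is the consensus span; under the default outer-bound merge
    rule it covers every member interval, and under any rule it must
    intersect each member.
    """

    sample_id: str
    interval: GenomicInterval
    cnv_type: CnvType
    supporting_algorithms: frozenset[str]
    member_calls: tuple[CnvCall, ...] = ()
    probe_count: int = 0

    def __post_init__(self) -> None:
        if not self.supporting_algorithms:
            raise ValueError("consensus call needs at least one algorithm")
        for m in self.member_calls:
            if m.sample_id != self.sample_id:
                raise ValueError("member call sample mismatch")
            if m.cnv_type is not self.cnv_type:
                raise ValueError("member call type mismatch")
            if (
                m.interval.chromosome != self.interval.chromosome
                or m.interval.end <= self.interval.start
                or m.interval.start >= self.interval.end
            ):
                raise ValueError("consensus interval disjoint from member")

    @property
    def n_algorithms(self) -> int:
        return len(self.supporting_algorithms)

    def sort_key(self) -> tuple:
        return (self.sample_id, *self.interval.sort_key())


@dataclass(frozen=True)
class ReferenceVariant:
    """A known structural variant with an optional population frequency.

    ``cnv_type`` of ``None`` matches either gain or loss.
    """

    variant_id: str
    interval: GenomicInterval
    cnv_type: Optional[CnvType] = None
    frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.frequency is not None and not (0.0 <= self.frequency <= 1.0):
            raise ValueError(f"frequency outside [0,1]: {self.frequency}")

    def matches_type(self, cnv_type: CnvType) -> bool:
        return self.cnv_type is None or self.cnv_type is cnv_type


class ReferenceVariantSet:
    """A named collection of reference variants with per-chromosome indices."""

    def __init__(self, name: str, variants: Iterable[ReferenceVariant]):
        self.name = name
        self.variants: tuple[ReferenceVariant, ...] = tuple(
            sorted(variants, key=lambda v: v.interval.sort_key())
        )
        self._trees: dict[str, IntervalTree] = {}
        for v in self.variants:
            tree = self._trees.setdefault(v.interval.chromosome, IntervalTree())
            tree.addi(v.interval.start, v.interval.end, v)

    def __len__(self) -> int:
        return len(self.variants)

    def overlapping(self, interval: GenomicInterval) -> list[ReferenceVariant]:
        tree = self._trees.get(interval.chromosome)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(interval.start, interval.end)]
        hits.sort(key=lambda v: (v.interval.sort_key(), v.variant_id))
        return hits


class ProbeManifest:
    """Array probe positions, indexed per chromosome for interval counting.

    Positions are stored 0-based internally; the on-disk manifest is 1-based.
    """

    def __init__(self, probe_ids: Sequence[str], chromosomes: Sequence[str], positions: Sequence[int]):
        if len({*probe_ids}) != len(probe_ids):
            raise ValueError("duplicate probe_id in manifest")
        order = sorted(
            range(len(probe_ids)),
            key=lambda i: (chromosome_rank(normalize_chromosome(chromosomes[i])), positions[i]),
        )
        self.probe_ids = tuple(probe_ids[i] for i in order)
        self._by_chrom: dict[str, tuple[np.ndarray, tuple[str, ...]]] = {}
        chrom_pos: dict[str, list[int]] = {}
        chrom_ids: dict[str, list[str]] = {}
        for i in order:
            c = normalize_chromosome(chromosomes[i])
            chrom_pos.setdefault(c, []).append(int(positions[i]))
            chrom_ids.setdefault(c, []).append(probe_ids[i])
        for c in chrom_pos:
            self._by_chrom[c] = (
                np.asarray(chrom_pos[c], dtype=np.int64),
                tuple(chrom_ids[c]),
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(sorted(self._by_chrom, key=chromosome_rank))

    def positions(self, chromosome: str) -> np.ndarray:
        return self._by_chrom[normalize_chromosome(chromosome)][0]

    def count_in(self, interval: GenomicInterval) -> int:
        """Number of probes whose position lies inside the half-open interval."""
        entry = self._by_chrom.get(interval.chromosome)
        if entry is None:
            return 0
        pos = entry[0]
        lo = int(np.searchsorted(pos, interval.start, side="left"))
        hi = int(np.searchsorted(pos, interval.end, side="left"))
        return hi - lo

    def probes_in(self, interval: GenomicInterval) -> tuple[str, ...]:
        entry = self._by_chrom.get(interval.chromosome)
        if entry is None:
            return ()
        pos, ids = entry
        lo = int(np.searchsorted(pos, interval.start, side="left"))
        hi = int(np.searchsorted(pos, interval.end, side="left"))
        return ids[lo:hi]

    def records(self):
        """Yield (probe_id, chromosome, position0) in genomic order."""
        for c in self.chromosomes:
            pos, ids = self._by_chrom[c]
            for pid, p in zip(ids, pos):
                yield pid, c, int(p)

    def flanking_probes(self, interval: GenomicInterval) -> tuple[str, str]:
        """First and last probe id inside the interval ('.' when empty)."""
        ids = self.probes_in(interval)
        if not ids:
            return (".", ".")
        return (ids[0], ids[-1])


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    symbol: str
    interval: GenomicInterval


class GenomeAnnotation:
    """Chromosome sizes, centromere/telomere intervals, GC track, gene models."""

    def __init__(
        self,
        chromosome_lengths: Mapping[str, int],
        centromeres: Mapping[str, GenomicInterval] | None = None,
        telomeres: Mapping[str, Sequence[GenomicInterval]] | None = None,
        gc_track: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
        genes: Iterable[GeneModel] = (),
    ):
        self.chromosome_lengths = {
            normalize_chromosome(c): int(n) for c, n in chromosome_lengths.items()
        }
        self.centromeres = dict(centromeres or {})
        self.telomeres = {c: tuple(ivs) for c, ivs in (telomeres or {}).items()}
        for iv in list(self.centromeres.values()) + [
            iv for ivs in self.telomeres.values() for iv in ivs
        ]:
            L = self.chromosome_lengths.get(iv.chromosome)
            if L is not None and iv.end > L:
                raise ValueError(f"annotation interval {iv} beyond chromosome end {L}")
        self._gc: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if gc_track:
            for c, (starts, ends, gc) in gc_track.items():
                gc = np.asarray(gc, dtype=float)
                if gc.size and (gc.min() < 0.0 or gc.max() > 1.0):
                    raise ValueError("GC fractions outside [0,1]")
                self._gc[normalize_chromosome(c)] = (
                    np.asarray(starts, dtype=np.int64),
                    np.asarray(ends, dtype=np.int64),
                    gc,
                )
        self.genes: tuple[GeneModel, ...] = tuple(
            sorted(genes, key=lambda g: g.interval.sort_key())
        )
        self._gene_trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            tree = self._gene_trees.setdefault(g.interval.chromosome, IntervalTree())
            tree.addi(g.interval.start, g.interval.end, g)

    @property
    def has_gc_track(self) -> bool:
        return bool(self._gc)

    def gc_windows(self, chromosome: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._gc[normalize_chromosome(chromosome)]

    def mean_gc(self, interval: GenomicInterval) -> Optional[float]:
        """Length-weighted mean GC of the track windows overlapping the interval.

        Returns ``None`` when the chromosome has no GC track or no window
        overlaps the interval.
        """
        entry = self._gc.get(interval.chromosome)
        if entry is None:
            return None
        starts, ends, gc = entry
        lo = int(np.searchsorted(ends, interval.start, side="right"))
        hi = int(np.searchsorted(starts, interval.end, side="left"))
        if hi <= lo:
            return None
        w_start = np.maximum(starts[lo:hi], interval.start)
        w_end = np.minimum(ends[lo:hi], interval.end)
        weights = (w_end - w_start).astype(float)
        total = weights.sum()
        if total <= 0:
            return None
        return float((gc[lo:hi] * weights).sum() / total)

    def centrotelo_gap(self, interval: GenomicInterval) -> Optional[int]:
        """Distance in bp to the nearest centromere/telomere interval (0 if
        overlapping); ``None`` when none is annotated for the chromosome."""
        features: list[GenomicInterval] = []
        cen = self.centromeres.get(interval.chromosome)
        if cen is not None:
            features.append(cen)
        features.extend(self.telomeres.get(interval.chromosome, ()))
        if not features:
            return None
        gaps = []
        for f in features:
            if f.start >= interval.end:
                gaps.append(f.start - interval.end)
            elif f.end <= interval.start:
                gaps.append(interval.start - f.end)
            else:
                gaps.append(0)
        return min(gaps)

    def genes_overlapping(self, interval: GenomicInterval) -> list[GeneModel]:
        tree = self._gene_trees.get(interval.chromosome)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(interval.start, interval.end)]
        hits.sort(key=lambda g: (g.interval.sort_key(), g.symbol))
        return hits


@dataclass(frozen=True)
class EchoMeasurements:
    """M-mode echocardiographic inputs for the Devereux LV mass estimate.

    Wall/chamber dimensions in cm, height in m (conventional echo units).
    """

    lvidd: float  # LV internal dimension, diastole (cm)
    pwtd: float  # posterior wall thickness, end-diastole (cm)
    ivstd: float  # interventricular septal thickness, end-diastole (cm)
    height: float  # m


GROUP_CASE = "case"
GROUP_CONTROL = "control"
SEX_MALE = "male"
SEX_FEMALE = "female"


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    group: str  # case | control
    sex: str  # male | female
    age: Optional[float] = None
    bmi: Optional[float] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    echo: Optional[EchoMeasurements] = None

    def __post_init__(self) -> None:
        if self.group not in (GROUP_CASE, GROUP_CONTROL):
            raise ValueError(f"unknown group label: {self.group!r}")
        if self.sex not in (SEX_MALE, SEX_FEMALE):
            raise ValueError(f"unknown sex label: {self.sex!r}")


def groups_of(samples: Iterable[SampleRecord]) -> dict[str, str]:
    """sample_id -> group mapping, asserting unique sample ids."""
    out: dict[str, str] = {}
    for s in samples:
        if s.sample_id in out:
            raise ValueError(f"duplicate sample_id: {s.sample_id}")
        out[s.sample_id] = s.group
    return out
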