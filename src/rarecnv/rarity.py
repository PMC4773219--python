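"""Rarity assessment, case/control specificity, recurrence and burden.

A filtered consensus call is *rare* (novel) when it

1. does not overlap any known copy-number polymorphism (CNP) with
   population frequency > 1% (any-overlap rule),
2. has < 50% reciprocal overlap (by length) with every variant in the
   reference sets (DGV-like, HapMap3-like, SGVP-like), and
3. occurs as a singleton across the genotyped cohort (no second sample
   carries a linked call of the same type).

The rules are applied in that fixed order and recorded separately so stage
tallies are auditable. Exactly 50% reciprocal overlap counts as *known*
(the exclusion is min-fraction >= f; configurable).

Case/control specificity and recurrence operate on the calls surviving
rules 1-2 (statuses ``rare`` and ``non_singleton``): a call is
group-specific when no opposite-group call of the same type links to it at
the 50% reciprocal-overlap linkage, and recurrent loci are linkage
clusters of group-specific calls spanning at least two distinct samples.
This keeps recurrent case loci — observed in 2-3 cases — inside the
case-specific set while the singleton rule still separates them from the
strictly rare calls.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import is_linked, outer_bounds, reciprocal_overlap, single_linkage_clusters
from .model import (
    CnvType,
    ConsensusCnv,
    GenomeAnnotation,
    GenomicInterval,
    GROUP_CASE,
    GROUP_CONTROL,
    ReferenceVariantSet,
)


class RarityStatus(str, Enum):
    RARE = "rare"
    KNOWN_CNP = "known_cnp"
    KNOWN_REFERENCE = "known_reference"
    NON_SINGLETON = "non_singleton"


@dataclass(frozen=True)
class RarityDecision:
    call: ConsensusCnv
    status: RarityStatus
    matched_reference_ids: tuple[str, ...] = ()


def filter_known_cnp(
    calls: Sequence[ConsensusCnv],
    cnp_set: ReferenceVariantSet,
    freq_threshold: float = 0.01,
    mode: str = "any_overlap",
    link_fraction: float = 0.5,
    match_type: bool = True,
) -> list[RarityDecision]:
    """Rule 1: mark calls overlapping a common CNP (frequency > threshold).

    ``mode='any_overlap'`` (default) excludes on >= 1 bp of overlap;
    ``mode='reciprocal'`` requires reciprocal overlap >= ``link_fraction``.
    """
    if mode not in ("any_overlap", "reciprocal"):
        raise ValueError(f"unknown CNP overlap mode: {mode!r}")
    out = []
    for c in calls:
        matched = []
        for v in cnp_set.overlapping(c.interval):
            if v.frequency is None or v.frequency <= freq_threshold:
                continue
            if match_type and not v.matches_type(c.cnv_type):
                continue
            if mode == "reciprocal" and not is_linked(
                c.interval, v.interval, link_fraction
            ):
                continue
            matched.append(v.variant_id)
        status = RarityStatus.KNOWN_CNP if matched else RarityStatus.RARE
        out.append(RarityDecision(c, status, tuple(matched)))
    return out


def filter_reference_overlap(
    calls: Sequence[ConsensusCnv],
    reference_sets: Sequence[ReferenceVariantSet],
    fraction: float = 0.5,
    match_type: bool = True,
) -> list[RarityDecision]:
    """Rule 2: mark calls with >= ``fraction`` reciprocal overlap to any
    reference variant, applied over the sets in the given order."""
    out = []
    for c in calls:
        matched: list[str] = []
        for ref in reference_sets:
            for v in ref.overlapping(c.interval):
                if match_type and not v.matches_type(c.cnv_type):
                    continue
                r = reciprocal_overlap(c.interval, v.interval)
                if r.overlap_bp > 0 and r.reciprocal_fraction >= fraction:
                    matched.append(f"{ref.name}:{v.variant_id}")
        status = RarityStatus.KNOWN_REFERENCE if matched else RarityStatus.RARE
        out.append(RarityDecision(c, status, tuple(matched)))
    return out


def find_singletons(
    calls: Sequence[ConsensusCnv], link_fraction: float = 0.5
) -> list[RarityDecision]:
    """Rule 3: mark calls whose occurrence cluster spans >= 2 distinct samples.

    Occurrence clusters are single-linkage clusters across samples within
    each (chromosome, type) stratum at ``link_fraction`` reciprocal overlap.
    """
    strata: dict[tuple, list[ConsensusCnv]] = {}
    for c in calls:
        strata.setdefault((c.interval.chromosome, c.cnv_type), []).append(c)
    non_singleton: set[int] = set()
    for members in strata.values():
        for cluster in single_linkage_clusters(members, lambda c: c.interval, link_fraction):
            if len({c.sample_id for c in cluster}) >= 2:
                non_singleton.update(id(c) for c in cluster)
    return [
        RarityDecision(
            c,
            RarityStatus.NON_SINGLETON if id(c) in non_singleton else RarityStatus.RARE,
        )
        for c in calls
    ]


def assess_rarity(
    calls: Sequence[ConsensusCnv],
    cnp_set: ReferenceVariantSet,
    reference_sets: Sequence[ReferenceVariantSet],
    freq_threshold: float = 0.01,
    reference_fraction: float = 0.5,
    link_fraction: float = 0.5,
    cnp_mode: str = "any_overlap",
) -> list[RarityDecision]:
    """Apply the three rarity rules in the fixed order CNP -> reference ->
    singleton; each call receives the first exclusion status that applies.

    The singleton rule is evaluated among the calls surviving rules 1-2,
    i.e. occurrence is counted over the study-unique call universe.
    """
    by_cnp = {id(d.call): d for d in filter_known_cnp(calls, cnp_set, freq_threshold, cnp_mode, link_fraction)}
    survivors1 = [c for c in calls if by_cnp[id(c)].status is RarityStatus.RARE]
    by_ref = {
        id(d.call): d
        for d in filter_reference_overlap(survivors1, reference_sets, reference_fraction)
    }
    survivors2 = [c for c in survivors1 if by_ref[id(c)].status is RarityStatus.RARE]
    by_single = {id(d.call): d for d in find_singletons(survivors2, link_fraction)}
    out = []
    for c in calls:
        d = by_cnp[id(c)]
        if d.status is not RarityStatus.RARE:
            out.append(d)
            continue
        d = by_ref[id(c)]
        if d.status is not RarityStatus.RARE:
            out.append(d)
            continue
        out.append(by_single[id(c)])
    return out


def study_unique_calls(decisions: Sequence[RarityDecision]) -> list[ConsensusCnv]:
    """Calls surviving the CNP and reference rules (rare or cohort-recurrent),
    the candidate universe for case/control specificity."""
    return [
        d.call
        for d in decisions
        if d.status in (RarityStatus.RARE, RarityStatus.NON_SINGLETON)
    ]


def case_control_specific(
    candidates: Sequence[ConsensusCnv],
    groups: Mapping[str, str],
    link_fraction: float = 0.5,
    background: Optional[Sequence[ConsensusCnv]] = None,
) -> tuple[list[ConsensusCnv], list[ConsensusCnv]]:
    """Split candidate calls into case-specific and control-specific sets.

    A candidate is group-specific when no ``background`` call (default: the
    candidates themselves; conservatively, pass the full retained consensus
    set) from the *opposite* group, of the same type, links to it at
    ``link_fraction`` reciprocal overlap.
    """
    bg = list(background) if background is not None else list(candidates)
    bg_strata: dict[tuple, list[ConsensusCnv]] = {}
    for c in bg:
        group = groups.get(c.sample_id)
        if group is None:
            raise KeyError(f"sample {c.sample_id} missing from group mapping")
        bg_strata.setdefault((group, c.interval.chromosome, c.cnv_type), []).append(c)
    case_specific: list[ConsensusCnv] = []
    control_specific: list[ConsensusCnv] = []
    for c in candidates:
        group = groups.get(c.sample_id)
        if group is None:
            raise KeyError(f"sample {c.sample_id} missing from group mapping")
        other = GROUP_CONTROL if group == GROUP_CASE else GROUP_CASE
        rivals = bg_strata.get((other, c.interval.chromosome, c.cnv_type), [])
        shared = any(is_linked(c.interval, r.interval, link_fraction) for r in rivals)
        if shared:
            continue
        (case_specific if group == GROUP_CASE else control_specific).append(c)
    case_specific.sort(key=lambda c: c.sort_key())
    control_specific.sort(key=lambda c: c.sort_key())
    return case_specific, control_specific


@dataclass(frozen=True)
class RecurrenceCluster:
    locus: GenomicInterval
    cnv_type: CnvType
    sample_ids: tuple[str, ...]
    n_cases: int
    n_controls: int
    genes: tuple[str, ...] = ()

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def find_recurrent(
    calls: Sequence[ConsensusCnv],
    groups: Mapping[str, str],
    min_samples: int = 2,
    link_fraction: float = 0.5,
    annotation: Optional[GenomeAnnotation] = None,
) -> list[RecurrenceCluster]:
    """Linkage clusters of (typically group-specific) calls observed in at
    least ``min_samples`` distinct samples, with outer-bound locus and the
    genes it disrupts."""
    strata: dict[tuple, list[ConsensusCnv]] = {}
    for c in calls:
        strata.setdefault((c.interval.chromosome, c.cnv_type), []).append(c)
    out: list[RecurrenceCluster] = []
    for (_, cnv_type), members in strata.items():
        for cluster in single_linkage_clusters(members, lambda c: c.interval, link_fraction):
            sample_ids = tuple(sorted({c.sample_id for c in cluster}))
            if len(sample_ids) < min_samples:
                continue
            locus = outer_bounds([c.interval for c in cluster])
            genes: tuple[str, ...] = ()
            if annotation is not None:
                genes = tuple(g.symbol for g in annotation.genes_overlapping(locus))
            out.append(
                RecurrenceCluster(
                    locus=locus,
                    cnv_type=cnv_type,
                    sample_ids=sample_ids,
                    n_cases=sum(groups.get(s) == GROUP_CASE for s in sample_ids),
                    n_controls=sum(groups.get(s) == GROUP_CONTROL for s in sample_ids),
                    genes=genes,
                )
            )
    out.sort(key=lambda r: (-r.n_samples, r.locus.sort_key()))
    return out


def annotate_genes(
    calls: Sequence[ConsensusCnv], annotation: GenomeAnnotation
) -> list[tuple[str, ...]]:
    """Symbols of genes intersecting each call by >= 1 bp (empty when none;
    rendered as a dash in reports)."""
    return [
        tuple(g.symbol for g in annotation.genes_overlapping(c.interval)) for c in calls
    ]


def genes_to_dash(symbols: Sequence[str]) -> str:
    return ",".join(symbols) if symbols else "-"


DEFAULT_SIZE_BINS_BP = (1_000, 10_000, 100_000, 1_000_000, 10_000_000)


@dataclass
class BurdenReport:
    """Per-group CNV totals, per-genome averages, length statistics and a
    size-bin percentage histogram, with a case-vs-control length test."""

    n_case_genomes: int
    n_control_genomes: int
    summary: pd.DataFrame  # one row per group
    histogram: pd.DataFrame  # bin_lo, bin_hi, case_pct, control_pct
    length_statistic: float
    length_p_value: float
    length_test: str


def _group_row(name: str, calls: Sequence[ConsensusCnv], n_genomes: int) -> dict:
    lengths = np.array([c.interval.length for c in calls], dtype=float)
    n_gain = sum(c.cnv_type is CnvType.GAIN for c in calls)
    n_loss = sum(c.cnv_type is CnvType.LOSS for c in calls)
    return {
        "group": name,
        "n_genomes": n_genomes,
        "n_cnvs": len(calls),
        "n_gain": n_gain,
        "n_loss": n_loss,
        "per_genome_mean": len(calls) / n_genomes if n_genomes else 0.0,
        "mean_length_bp": float(lengths.mean()) if lengths.size else 0.0,
        "median_length_bp": float(np.median(lengths)) if lengths.size else 0.0,
        "min_length_bp": int(lengths.min()) if lengths.size else 0,
        "max_length_bp": int(lengths.max()) if lengths.size else 0,
    }


def burden_report(
    case_calls: Sequence[ConsensusCnv],
    control_calls: Sequence[ConsensusCnv],
    n_case_genomes: int,
    n_control_genomes: int,
    size_bins_bp: Sequence[int] = DEFAULT_SIZE_BINS_BP,
    length_test: str = "welch",
) -> BurdenReport:
    """Group burden statistics.

    Per-genome means are group totals over group genome counts (e.g. 208
    calls over 44 genomes renders 4.72). The length comparison defaults to
    Welch's t-test (``length_test='mannwhitney'`` for the rank-based
    alternative); identical length samples give statistic 0, p = 1.
    """
    if n_case_genomes < 0 or n_control_genomes < 0:
        raise ValueError("genome counts must be >= 0")
    summary = pd.DataFrame(
        [
            _group_row("case", case_calls, n_case_genomes),
            _group_row("control", control_calls, n_control_genomes),
        ]
    )
    edges = np.asarray(list(size_bins_bp), dtype=float)
    rows = []
    case_len = np.array([c.interval.length for c in case_calls], dtype=float)
    ctrl_len = np.array([c.interval.length for c in control_calls], dtype=float)
    for lo, hi in zip(edges[:-1], edges[1:]):
        rows.append(
            {
                "bin_lo_bp": int(lo),
                "bin_hi_bp": int(hi),
                "case_pct": 100.0 * np.mean((case_len >= lo) & (case_len < hi))
                if case_len.size
                else 0.0,
                "control_pct": 100.0 * np.mean((ctrl_len >= lo) & (ctrl_len < hi))
                if ctrl_len.size
                else 0.0,
            }
        )
    hist = pd.DataFrame(rows)
    if case_len.size < 2 or ctrl_len.size < 2:
        stat, p = float("nan"), float("nan")
    elif (
        case_len.size == ctrl_len.size
        and np.array_equal(np.sort(case_len), np.sort(ctrl_len))
    ) or (np.ptp(case_len) == 0 and np.ptp(ctrl_len) == 0 and case_len[0] == ctrl_len[0]):
        stat, p = 0.0, 1.0
    elif length_test == "welch":
        s, p = stats.ttest_ind(case_len, ctrl_len, equal_var=False)
        stat, p = float(s), float(p)
    elif length_test == "mannwhitney":
        s, p = stats.mannwhitneyu(case_len, ctrl_len, alternative="two-sided")
        stat, p = float(s), float(p)
    else:
        raise ValueError(f"unknown length test: {length_test!r}")
    return BurdenReport(
        n_case_genomes=n_case_genomes,
        n_control_genomes=n_control_genomes,
        summary=summary,
        histogram=hist,
        length_statistic=stat,
        length_p_value=p,
        length_test=length_test,
    )


def rarity_tally(decisions: Sequence[RarityDecision]) -> pd.DataFrame:
    counts = {s: 0 for s in RarityStatus}
    for d in decisions:
        counts[d.status] += 1
    rows = [{"category": "input", "n": len(decisions)}]
    rows += [{"category": s.value, "n": counts[s]} for s in RarityStatus]
    return pd.DataFrame(rows)
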