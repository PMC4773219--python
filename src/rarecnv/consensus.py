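"""Multi-algorithm consensus merging and CNV-level filtering.

Calls from the three detection algorithms are merged within each
(sample, chromosome, CNV type) stratum by single-linkage clustering at 50%
reciprocal overlap; a cluster becomes a "stringent" consensus call when it
is supported by at least two distinct algorithms. Consensus calls then pass
through five exclusion rules:

* fewer than 5 probes (FEW_PROBES)
* mean GC of the overlapped track windows > 0.70 (HIGH_GC)
* within 30 kb of a centromere or telomere (CENTROTELO)
* shorter than 1 kb (TOO_SMALL)
* on a sex chromosome (SEX_CHROM)

plus the implicit single-algorithm rule (already enforced at merge time).
Calls longer than 1 Mb are flagged for review rather than auto-excluded,
standing in for the manual inspection such calls receive in practice; an
optional hard cap can exclude them outright.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .intervals import outer_bounds, single_linkage_clusters
from .model import (
    CnvCall,
    ConsensusCnv,
    GenomeAnnotation,
    GenomicInterval,
    ProbeManifest,
    SEX_CHROMOSOMES,
)

logger = logging.getLogger(__name__)


class FilterReason(str, Enum):
    FEW_PROBES = "FEW_PROBES"
    HIGH_GC = "HIGH_GC"
    CENTROTELO = "CENTROTELO"
    TOO_SMALL = "TOO_SMALL"
    SEX_CHROM = "SEX_CHROM"
    SINGLE_ALGORITHM = "SINGLE_ALGORITHM"
    LARGE_CALL = "LARGE_CALL"  # only with an explicit hard cap


@dataclass(frozen=True)
class FilterParams:
    min_probes: int = 5
    max_gc: float = 0.70
    centrotelo_margin_bp: int = 30_000
    min_length_bp: int = 1_000
    exclude_sex_chromosomes: bool = True
    min_support: int = 2
    large_call_review_bp: int = 1_000_000
    large_call_cap_bp: Optional[int] = None  # None: flag only, never exclude


@dataclass(frozen=True)
class FilterOutcome:
    call: ConsensusCnv
    retained: bool
    exclusion_reasons: frozenset[FilterReason] = frozenset()
    large_call_review: bool = False

    def __post_init__(self) -> None:
        if self.retained != (not self.exclusion_reasons):
            raise ValueError("retained must match empty exclusion_reasons")


def _consensus_interval(
    members: Sequence[CnvCall], boundary: str
) -> GenomicInterval:
    ivs = [m.interval for m in members]
    if boundary == "outer":
        return outer_bounds(ivs)
    if boundary == "intersection":
        chrom = ivs[0].chromosome
        start = max(iv.start for iv in ivs)
        end = min(iv.end for iv in ivs)
        if end > start:
            return GenomicInterval(chrom, start, end)
        return outer_bounds(ivs)  # chained cluster with empty common core
    if boundary == "median":
        starts = sorted(iv.start for iv in ivs)
        ends = sorted(iv.end for iv in ivs)
        start = starts[len(starts) // 2]
        end = ends[len(ends) // 2]
        if end > start:
            return GenomicInterval(ivs[0].chromosome, start, end)
        return outer_bounds(ivs)
    raise ValueError(f"unknown boundary rule: {boundary!r}")


def merge_algorithm_calls(
    callsets: Iterable[Sequence[CnvCall]] | Sequence[CnvCall],
    min_support: int = 2,
    link_fraction: float = 0.5,
    boundary: str = "outer",
) -> list[ConsensusCnv]:
    """Merge per-algorithm call sets into stringent consensus calls.

    Within each (sample, chromosome, type) stratum, calls are clustered by
    single linkage at ``link_fraction`` reciprocal overlap; each cluster
    supported by >= ``min_support`` distinct algorithms yields one consensus
    call whose interval follows the ``boundary`` rule ("outer" by default:
    the cluster's outer bounds; members always remain covered, so
    "intersection"/"median" fall back to outer bounds when degenerate).

    Exact duplicate (algorithm, sample, interval, type) calls are collapsed
    with a warning. Output is sorted by (sample, chromosome, start).
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    flat: list[CnvCall] = []
    for item in callsets:
        if isinstance(item, CnvCall):
            flat.append(item)
        else:
            flat.extend(item)
    seen: set[tuple] = set()
    calls: list[CnvCall] = []
    n_dup = 0
    for c in flat:
        key = (c.algorithm, c.sample_id, c.interval, c.cnv_type)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        calls.append(c)
    if n_dup:
        logger.warning("collapsed %d duplicate (algorithm, sample, interval) calls", n_dup)

    strata: dict[tuple, list[CnvCall]] = {}
    for c in calls:
        strata.setdefault((c.sample_id, c.interval.chromosome, c.cnv_type), []).append(c)

    out: list[ConsensusCnv] = []
    for (sample_id, _chrom, cnv_type), members in strata.items():
        for cluster in single_linkage_clusters(members, lambda c: c.interval, link_fraction):
            support = frozenset(c.algorithm for c in cluster)
            if len(support) < min_support:
                continue
            out.append(
                ConsensusCnv(
                    sample_id=sample_id,
                    interval=_consensus_interval(cluster, boundary),
                    cnv_type=cnv_type,
                    supporting_algorithms=support,
                    member_calls=tuple(sorted(cluster, key=lambda c: c.sort_key())),
                )
            )
    out.sort(key=lambda c: c.sort_key())
    return out


def count_merge_clusters(
    callsets: Iterable[Sequence[CnvCall]] | Sequence[CnvCall],
    link_fraction: float = 0.5,
) -> int:
    """Total number of cross-algorithm clusters (any support level)."""
    return len(merge_algorithm_calls(callsets, min_support=1, link_fraction=link_fraction))


def annotate_probe_counts(calls: Sequence, manifest: ProbeManifest) -> list:
    """Return calls with ``probe_count`` set from the manifest.

    Works for both raw and consensus calls; a chromosome absent from the
    manifest yields probe_count 0 with a warning.
    """
    missing: Counter[str] = Counter()
    out = []
    for c in calls:
        n = manifest.count_in(c.interval)
        if n == 0 and c.interval.chromosome not in manifest.chromosomes:
            missing[c.interval.chromosome] += 1
        out.append(replace(c, probe_count=n))
    for chrom, k in missing.items():
        logger.warning("%d calls on %s, which has no manifest probes", k, chrom)
    return out


def apply_cnv_filters(
    calls: Sequence[ConsensusCnv],
    annotation: GenomeAnnotation,
    params: FilterParams = FilterParams(),
) -> tuple[list[FilterOutcome], pd.DataFrame]:
    """Apply the five CNV-level exclusion rules to probe-annotated calls.

    Returns per-call outcomes plus a tally table in which the input count
    equals retained + excluded (a call excluded for several reasons counts
    once in the total and once per reason in the breakdown).
    """
    if not annotation.has_gc_track:
        logger.warning("no GC track in annotation: HIGH_GC filter skipped")
    outcomes: list[FilterOutcome] = []
    reason_counts: Counter[FilterReason] = Counter()
    n_review = 0
    for c in calls:
        reasons: set[FilterReason] = set()
        if c.probe_count < params.min_probes:
            reasons.add(FilterReason.FEW_PROBES)
        if annotation.has_gc_track:
            gc = annotation.mean_gc(c.interval)
            if gc is not None and gc > params.max_gc:
                reasons.add(FilterReason.HIGH_GC)
        gap = annotation.centrotelo_gap(c.interval)
        if gap is not None and gap < params.centrotelo_margin_bp:
            reasons.add(FilterReason.CENTROTELO)
        if c.interval.length < params.min_length_bp:
            reasons.add(FilterReason.TOO_SMALL)
        if params.exclude_sex_chromosomes and c.interval.chromosome in SEX_CHROMOSOMES:
            reasons.add(FilterReason.SEX_CHROM)
        if c.n_algorithms < params.min_support:
            reasons.add(FilterReason.SINGLE_ALGORITHM)
        review = c.interval.length > params.large_call_review_bp
        if review:
            n_review += 1
            if (
                params.large_call_cap_bp is not None
                and c.interval.length > params.large_call_cap_bp
            ):
                reasons.add(FilterReason.LARGE_CALL)
        for r in reasons:
            reason_counts[r] += 1
        outcomes.append(
            FilterOutcome(
                call=c,
                retained=not reasons,
                exclusion_reasons=frozenset(reasons),
                large_call_review=review,
            )
        )
    n_input = len(outcomes)
    n_retained = sum(o.retained for o in outcomes)
    rows = [
        {"category": "input", "n": n_input},
        {"category": "retained", "n": n_retained},
        {"category": "excluded", "n": n_input - n_retained},
    ]
    for r in FilterReason:
        rows.append({"category": f"excluded_{r.value}", "n": reason_counts.get(r, 0)})
    rows.append({"category": "flagged_large_call", "n": n_review})
    return outcomes, pd.DataFrame(rows)


def retained_calls(outcomes: Sequence[FilterOutcome]) -> list[ConsensusCnv]:
    return [o.call for o in outcomes if o.retained]
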