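"""End-to-end orchestration: QC -> consensus merge -> interval filters ->
aggregate-length outliers -> rarity -> case/control specificity ->
recurrence -> burden, with conserving stage-by-stage bookkeeping."""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from typing import Mapping, Optional, Sequence

import pandas as pd

from .consensus import (
    FilterOutcome,
    FilterParams,
    annotate_probe_counts,
    apply_cnv_filters,
    merge_algorithm_calls,
    retained_calls,
)
from .model import (
    CnvCall,
    ConsensusCnv,
    GenomeAnnotation,
    GROUP_CASE,
    GROUP_CONTROL,
    ProbeManifest,
    ReferenceVariantSet,
    SampleRecord,
    groups_of,
)
from .qc import (
    QcDecision,
    QcMetrics,
    QcThresholds,
    SampleSignals,
    apply_sample_qc,
    compute_cohort_qc,
    exclude_length_outliers,
)
from .rarity import (
    BurdenReport,
    RarityDecision,
    RarityStatus,
    RecurrenceCluster,
    assess_rarity,
    burden_report,
    case_control_specific,
    find_recurrent,
    rarity_tally,
    study_unique_calls,
)

logger = logging.getLogger(__name__)


def _package_version() -> str:
    try:
        return _pkg_version("rarecnv")
    except PackageNotFoundError:  # pragma: no cover - dev tree
        return "unknown"


@dataclass(frozen=True)
class PipelineParams:
    """All tunables of the discovery workflow with their standard defaults."""

    qc: QcThresholds = QcThresholds()
    filters: FilterParams = FilterParams()
    link_fraction: float = 0.5
    min_support: int = 2
    cnp_freq_threshold: float = 0.01
    reference_fraction: float = 0.5
    length_test: str = "welch"


@dataclass
class StageCount:
    stage: str
    n_input: int
    n_retained: int
    n_excluded: int
    detail: dict = field(default_factory=dict)

    def conserves(self) -> bool:
        return self.n_input == self.n_retained + self.n_excluded


@dataclass
class RunManifest:
    """Stage-by-stage counts for a pipeline run.

    Serialized manifests deliberately carry no wall-clock timestamp so that
    identical (config, seed) runs produce byte-identical output trees.
    """

    seed: Optional[int] = None
    version: str = field(default_factory=_package_version)
    stages: list[StageCount] = field(default_factory=list)

    def add(self, stage: str, n_input: int, n_retained: int, detail: Optional[dict] = None) -> None:
        sc = StageCount(stage, n_input, n_retained, n_input - n_retained, detail or {})
        self.stages.append(sc)

    def conserves(self) -> bool:
        return all(s.conserves() for s in self.stages)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "version": self.version,
            "stages": [dataclasses.asdict(s) for s in self.stages],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class PipelineResult:
    params: PipelineParams
    qc_metrics: list[QcMetrics]
    qc_decisions: list[QcDecision]
    kept_samples: set[str]
    consensus: list[ConsensusCnv]
    filter_outcomes: list[FilterOutcome]
    filter_tally: pd.DataFrame
    retained: list[ConsensusCnv]
    rarity_decisions: list[RarityDecision]
    rarity_tally: pd.DataFrame
    case_specific: list[ConsensusCnv]
    control_specific: list[ConsensusCnv]
    recurrent: list[RecurrenceCluster]
    burden: BurdenReport
    manifest: RunManifest


def aggregate_cnv_lengths(calls: Sequence[ConsensusCnv]) -> dict[str, int]:
    out: dict[str, int] = {}
    for c in calls:
        out[c.sample_id] = out.get(c.sample_id, 0) + c.interval.length
    return out


def run_pipeline(
    callsets: Mapping[str, Sequence[CnvCall]],
    samples: Sequence[SampleRecord],
    annotation: GenomeAnnotation,
    probe_manifest: ProbeManifest,
    reference_sets: Mapping[str, ReferenceVariantSet],
    signals: Optional[Mapping[str, SampleSignals]] = None,
    qc_metrics: Optional[Sequence[QcMetrics]] = None,
    params: PipelineParams = PipelineParams(),
    seed: Optional[int] = None,
) -> PipelineResult:
    """Run the full discovery workflow in memory.

    ``reference_sets`` is an ordered mapping; the first set doubles as the
    CNP catalogue for the frequency rule, and all sets are used for the
    reciprocal-overlap novelty rule. Sample QC needs either raw ``signals``
    or precomputed ``qc_metrics``; with neither, all samples are kept.
    """
    manifest = RunManifest(seed=seed)
    groups = groups_of(samples)

    # ---- sample QC -------------------------------------------------------
    if qc_metrics is None and signals is not None:
        qc_metrics = compute_cohort_qc(signals)
    if qc_metrics is None:
        logger.warning("no QC signals or metrics supplied: keeping all samples")
        qc_metrics = []
        decisions = [QcDecision(s.sample_id, kept=True) for s in samples]
    else:
        decisions = apply_sample_qc(qc_metrics, params.qc)
    kept = {d.sample_id for d in decisions if d.kept}
    manifest.add(
        "sample_qc",
        len(decisions),
        len(kept),
        {
            "failed": sorted(
                {r.value for d in decisions for r in d.failure_reasons}
            )
        },
    )

    # ---- consensus merge (kept samples only) -----------------------------
    input_calls = [
        c for calls in callsets.values() for c in calls if c.sample_id in kept
    ]
    all_clusters = merge_algorithm_calls(
        input_calls, min_support=1, link_fraction=params.link_fraction
    )
    consensus = [c for c in all_clusters if c.n_algorithms >= params.min_support]
    manifest.add(
        "consensus_merge",
        len(all_clusters),
        len(consensus),
        {"n_raw_calls": len(input_calls)},
    )

    # ---- CNV-level filters ----------------------------------------------
    consensus = annotate_probe_counts(consensus, probe_manifest)
    outcomes, tally = apply_cnv_filters(consensus, annotation, params.filters)
    retained = retained_calls(outcomes)
    manifest.add(
        "cnv_filters",
        len(outcomes),
        len(retained),
        {r["category"]: int(r["n"]) for _, r in tally.iterrows()},
    )

    # ---- aggregate-length outlier exclusion ------------------------------
    lengths = aggregate_cnv_lengths(retained)
    decisions2 = exclude_length_outliers(
        decisions, lengths, params.qc.length_outlier_iqr_multiplier
    )
    kept2 = {d.sample_id for d in decisions2 if d.kept}
    n_before = len(retained)
    retained = [c for c in retained if c.sample_id in kept2]
    qc_metrics = [
        dataclasses.replace(m, aggregate_cnv_length=lengths.get(m.sample_id, 0))
        for m in qc_metrics
    ]
    manifest.add(
        "length_outliers",
        n_before,
        len(retained),
        {"samples_excluded": sorted(kept - kept2)},
    )

    # ---- rarity ----------------------------------------------------------
    ref_list = list(reference_sets.values())
    if not ref_list:
        raise ValueError("at least one reference set is required")
    rarity = assess_rarity(
        retained,
        cnp_set=ref_list[0],
        reference_sets=ref_list,
        freq_threshold=params.cnp_freq_threshold,
        reference_fraction=params.reference_fraction,
        link_fraction=params.link_fraction,
    )
    r_tally = rarity_tally(rarity)
    candidates = study_unique_calls(rarity)
    manifest.add(
        "rarity",
        len(rarity),
        len(candidates),
        {r["category"]: int(r["n"]) for _, r in r_tally.iterrows()},
    )

    # ---- case/control specificity ---------------------------------------
    case_specific, control_specific = case_control_specific(
        candidates, groups, params.link_fraction, background=retained
    )
    manifest.add(
        "specificity",
        len(candidates),
        len(case_specific) + len(control_specific),
        {"case_specific": len(case_specific), "control_specific": len(control_specific)},
    )

    # ---- recurrence ------------------------------------------------------
    recurrent = find_recurrent(
        case_specific, groups, min_samples=2,
        link_fraction=params.link_fraction, annotation=annotation,
    )
    manifest.add(
        "recurrence",
        len(case_specific),
        len(case_specific),
        {"n_recurrent_loci": len(recurrent)},
    )

    # ---- burden ----------------------------------------------------------
    n_case = sum(1 for s in samples if s.group == GROUP_CASE and s.sample_id in kept2)
    n_control = sum(
        1 for s in samples if s.group == GROUP_CONTROL and s.sample_id in kept2
    )
    burden = burden_report(
        case_specific,
        control_specific,
        n_case,
        n_control,
        length_test=params.length_test,
    )
    manifest.add(
        "burden",
        len(case_specific) + len(control_specific),
        len(case_specific) + len(control_specific),
        {
            "case_per_genome": round(len(case_specific) / n_case, 2) if n_case else 0.0,
            "control_per_genome": round(len(control_specific) / n_control, 2)
            if n_control
            else 0.0,
        },
    )

    return PipelineResult(
        params=params,
        qc_metrics=list(qc_metrics),
        qc_decisions=decisions2,
        kept_samples=kept2,
        consensus=consensus,
        filter_outcomes=outcomes,
        filter_tally=tally,
        retained=retained,
        rarity_decisions=rarity,
        rarity_tally=r_tally,
        case_specific=case_specific,
        control_specific=control_specific,
        recurrent=recurrent,
        burden=burden,
        manifest=manifest,
    )
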