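"""Per-sample SNP-array quality control.

A sample is excluded when any of the following holds (strict directions,
boundary values pass):

* genotype call rate < 0.99
* standard deviation of autosomal log R ratio (LRR) > 0.35
* standard deviation of B allele frequency (BAF) over the heterozygous
  band [0.25, 0.75] > 0.13
* cross-sample batch-normalized intensity-ratio SD > 0.27

After consensus calling, samples that are upper outliers with respect to
their aggregate CNV length (Tukey fence Q3 + 3*IQR over the kept samples)
are additionally excluded.

Notes on the estimators: the BAF SD is restricted to the heterozygous band
because the homozygous clusters at 0 and 1 would otherwise dominate the
statistic and make a 0.13 threshold meaningless; the batch-normalized
ratio SD is the SD of each sample's per-probe intensity ratio divided by
the batch median profile, a surrogate for the array-processing metric of
the same name whose exact formula is not published.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

BAF_HET_BAND = (0.25, 0.75)


class QcFailure(str, Enum):
    CALL_RATE = "CALL_RATE"
    LRR_SD = "LRR_SD"
    BAF_SD = "BAF_SD"
    BATCH_RATIO_SD = "BATCH_RATIO_SD"
    LENGTH_OUTLIER = "LENGTH_OUTLIER"


@dataclass(frozen=True)
class QcThresholds:
    min_call_rate: float = 0.99
    max_lrr_sd: float = 0.35
    max_baf_sd: float = 0.13
    max_batch_ratio_sd: float = 0.27
    length_outlier_iqr_multiplier: float = 3.0

    def __post_init__(self) -> None:
        for f in (
            self.min_call_rate,
            self.max_lrr_sd,
            self.max_baf_sd,
            self.max_batch_ratio_sd,
            self.length_outlier_iqr_multiplier,
        ):
            if f <= 0:
                raise ValueError("QC thresholds must be positive")


@dataclass(frozen=True)
class QcMetrics:
    sample_id: str
    call_rate: float
    lrr_sd: float
    baf_sd: float
    batch_ratio_sd: float
    aggregate_cnv_length: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.call_rate <= 1.0):
            raise ValueError(f"call_rate outside [0,1]: {self.call_rate}")
        for name in ("lrr_sd", "baf_sd", "batch_ratio_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name}")


@dataclass(frozen=True)
class QcDecision:
    sample_id: str
    kept: bool
    failure_reasons: frozenset[QcFailure] = frozenset()

    def __post_init__(self) -> None:
        if self.kept != (not self.failure_reasons):
            raise ValueError("kept must match empty failure_reasons")


@dataclass(frozen=True)
class SampleSignals:
    """Per-probe signal vectors for one sample (autosomal probes).

    ``intensity_ratio`` is the per-probe total-intensity ratio used for the
    batch-normalization metric; ``called`` flags probes with a genotype call.
    """

    lrr: np.ndarray
    baf: np.ndarray
    called: np.ndarray
    intensity_ratio: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.lrr)
        if n == 0:
            raise ValueError("empty signal vectors")
        if not (len(self.baf) == len(self.called) == len(self.intensity_ratio) == n):
            raise ValueError("signal vectors must share length")


def _sd(x: np.ndarray) -> float:
    if x.size < 2 or np.ptp(x) == 0:
        return 0.0
    return float(np.std(x, ddof=1))


def compute_qc_metrics(
    sample_id: str,
    signals: SampleSignals,
    batch_median_profile: Optional[np.ndarray] = None,
) -> QcMetrics:
    """QC metrics for one sample.

    ``batch_median_profile`` is the per-probe median intensity ratio across
    the batch (see :func:`compute_cohort_qc`); without it the batch metric
    is reported as 0.
    """
    call_rate = float(np.mean(signals.called.astype(bool)))
    lrr_sd = _sd(np.asarray(signals.lrr, dtype=float))
    baf = np.asarray(signals.baf, dtype=float)
    band = baf[(baf >= BAF_HET_BAND[0]) & (baf <= BAF_HET_BAND[1])]
    baf_sd = _sd(band)
    if batch_median_profile is None:
        batch_ratio_sd = 0.0
    else:
        profile = np.clip(np.asarray(batch_median_profile, dtype=float), 1e-9, None)
        batch_ratio_sd = _sd(np.asarray(signals.intensity_ratio, dtype=float) / profile)
    return QcMetrics(
        sample_id=sample_id,
        call_rate=call_rate,
        lrr_sd=lrr_sd,
        baf_sd=baf_sd,
        batch_ratio_sd=batch_ratio_sd,
    )


def batch_median_profile(signals: Mapping[str, SampleSignals]) -> np.ndarray:
    """Per-probe median intensity ratio across all samples of a batch."""
    if not signals:
        raise ValueError("empty batch")
    ratios = np.vstack([s.intensity_ratio for s in signals.values()])
    return np.median(ratios, axis=0)


def compute_cohort_qc(signals: Mapping[str, SampleSignals]) -> list[QcMetrics]:
    """QC metrics for every sample in a batch, normalizing ratios to the
    batch median profile."""
    profile = batch_median_profile(signals)
    return [
        compute_qc_metrics(sample_id, s, batch_median_profile=profile)
        for sample_id, s in signals.items()
    ]


def apply_sample_qc(
    metrics: Sequence[QcMetrics], thresholds: QcThresholds = QcThresholds()
) -> list[QcDecision]:
    """Threshold the metrics with the documented strict directions.

    A sample fails iff call_rate < min_call_rate, or any SD metric is
    strictly above its maximum; values exactly at a bound pass.
    """
    decisions = []
    for m in metrics:
        reasons = set()
        if m.call_rate < thresholds.min_call_rate:
            reasons.add(QcFailure.CALL_RATE)
        if m.lrr_sd > thresholds.max_lrr_sd:
            reasons.add(QcFailure.LRR_SD)
        if m.baf_sd > thresholds.max_baf_sd:
            reasons.add(QcFailure.BAF_SD)
        if m.batch_ratio_sd > thresholds.max_batch_ratio_sd:
            reasons.add(QcFailure.BATCH_RATIO_SD)
        decisions.append(
            QcDecision(m.sample_id, kept=not reasons, failure_reasons=frozenset(reasons))
        )
    return decisions


def exclude_length_outliers(
    decisions: Sequence[QcDecision],
    aggregate_lengths: Mapping[str, int],
    iqr_multiplier: float = 3.0,
) -> list[QcDecision]:
    """Flag kept samples whose aggregate CNV length is an upper outlier.

    The fence is Q3 + ``iqr_multiplier`` * IQR over the currently kept
    samples (a sample with no calls contributes 0 and can never be an
    upper outlier). With fewer than 4 kept samples no test is performed.
    """
    kept_ids = [d.sample_id for d in decisions if d.kept]
    if len(kept_ids) < 4:
        logger.warning(
            "only %d kept samples; skipping aggregate-length outlier test",
            len(kept_ids),
        )
        return list(decisions)
    lengths = np.array([aggregate_lengths.get(s, 0) for s in kept_ids], dtype=float)
    q1, q3 = np.percentile(lengths, [25, 75])
    fence = q3 + iqr_multiplier * (q3 - q1)
    outliers = {s for s, L in zip(kept_ids, lengths) if L > fence}
    out = []
    for d in decisions:
        if d.sample_id in outliers:
            out.append(
                QcDecision(
                    d.sample_id,
                    kept=False,
                    failure_reasons=d.failure_reasons | {QcFailure.LENGTH_OUTLIER},
                )
            )
        else:
            out.append(d)
    return out
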