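"""Synthetic study generator with a ground-truth ledger.

Everything the pipeline consumes is generated here at desk scale: a small
genome scaffold (a few chromosomes with centromeres, telomeres, a windowed
GC track and ~20,000 array probes, standing in for a genotyping-array
manifest), DGV/HapMap3/SGVP-like reference variant sets, a case-control
cohort with echocardiographic phenotypes, a planted CNV landscape (common
polymorphisms, shared rare loci, per-sample singletons and recurrent
case-only loci), per-sample QC signal vectors with optional failure
injections, and three imperfect "calling algorithms" that emit the planted
CNVs with configurable sensitivity, breakpoint jitter and false-positive
rate.

The generator emits *call sets*, not raw probe intensities: the detection
algorithms proper (segmentation HMMs) are outside the pipeline, which
consumes their output. LRR/BAF/ratio vectors are generated only to
exercise the sample QC metrics.

All randomness flows from one seed; identical (config, seed) gives
identical outputs, ledger included. The TruthLedger records every planted
CNV with its class, the provenance of every emitted call (true or false
positive), injected QC failures and the phenotype ground truth, enabling
exact recovery checks downstream.
"""
from __future__ import annotations

import dataclasses
import logging
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    AUTOSOMES,
    CnvCall,
    CnvType,
    EchoMeasurements,
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    GROUP_CASE,
    GROUP_CONTROL,
    ProbeManifest,
    ReferenceVariant,
    ReferenceVariantSet,
    SEX_FEMALE,
    SEX_MALE,
    SampleRecord,
    chromosome_rank,
)
from .phenotype import LvhThresholds, classify_lvh, compute_lv_mass, compute_lvmi
from .qc import QcFailure, SampleSignals

logger = logging.getLogger(__name__)

CLASS_CNP = "cnp"
CLASS_SHARED_RARE = "shared_rare"
CLASS_SINGLETON = "singleton"
CLASS_RECURRENT_CASE = "recurrent_case"

ORIGIN_TRUE = "true_positive"
ORIGIN_FALSE = "false_positive"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults reproduce the design of the modelled study at desk scale:
    a 44-case / 72-control hypertensive cohort (116 genomes), three
    imperfect calling algorithms, common CNPs at frequency > 1% recorded
    in the reference sets, a handful of loci shared between one case and
    one control, per-genome singleton rates, and three recurrent
    case-only loci carried by 3, 2 and 2 cases.
    """

    seed: int
    # genome scaffold
    chromosome_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 40_000_000, "chr2": 30_000_000, "chrX": 12_000_000}
    )
    probe_spacing_bp: int = 4_000
    telomere_bp: int = 50_000
    centromere_bp: int = 2_000_000
    gc_window_bp: int = 10_000
    gc_mean: float = 0.42
    gc_sd: float = 0.05
    high_gc_rate: float = 0.01
    n_genes: int = 200
    gene_length_range_bp: tuple[int, int] = (5_000, 60_000)
    # cohort
    n_case: int = 44
    n_control: int = 72
    p_male_case: float = 0.84
    p_male_control: float = 0.67
    phenotype_error_rate: float = 0.0
    # planted CNV landscape
    n_cnp_loci: int = 30
    cnp_frequency_range: tuple[float, float] = (0.02, 0.40)
    n_shared_rare_loci: int = 5
    case_singleton_rate: float = 2.0
    control_singleton_rate: float = 1.7
    recurrent_case_carriers: tuple[int, ...] = (3, 2, 2)
    cnv_length_range_bp: tuple[int, int] = (30_000, 120_000)
    loss_fraction: float = 0.8
    locus_gap_bp: int = 50_000
    # reference sets
    n_decoy_reference: int = 40
    # calling algorithms
    algorithms: tuple[str, ...] = ("cnvpartition", "penncnv", "ipattern")
    sensitivity: float = 0.95
    breakpoint_jitter: float = 0.10
    fp_per_genome: float = 2.0
    # QC signals
    qc_probe_count: int = 4_000
    qc_failure_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "phenotype_error_rate", "high_gc_rate", "sensitivity",
            "breakpoint_jitter", "qc_failure_rate", "loss_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        lo, hi = self.cnp_frequency_range
        if lo <= 0.01:
            raise ValueError("CNP frequencies must exceed 0.01 (the CNP definition)")
        if hi > 1.0 or lo > hi:
            raise ValueError("bad cnp_frequency_range")

    def noiseless(self) -> "SimulationConfig":
        """The same study with perfect callers (sensitivity 1, no jitter,
        no false positives)."""
        return dataclasses.replace(
            self, sensitivity=1.0, breakpoint_jitter=0.0, fp_per_genome=0.0
        )


@dataclass(frozen=True)
class TruthCnv:
    locus_id: str
    sample_id: str
    interval: GenomicInterval
    cnv_type: CnvType
    copy_number: int
    cnv_class: str  # cnp | shared_rare | singleton | recurrent_case


@dataclass(frozen=True)
class EmittedCall:
    algorithm: str
    sample_id: str
    interval: GenomicInterval
    cnv_type: CnvType
    origin: str  # true_positive | false_positive
    locus_id: Optional[str] = None


@dataclass
class TruthLedger:
    cnvs: list[TruthCnv] = field(default_factory=list)
    emitted: list[EmittedCall] = field(default_factory=list)
    qc_failures: dict[str, tuple[str, ...]] = field(default_factory=dict)
    phenotypes: dict[str, bool] = field(default_factory=dict)  # sample -> is LVH

    def entries_of_class(self, *classes: str) -> list[TruthCnv]:
        return [t for t in self.cnvs if t.cnv_class in classes]

    def expected_specific(
        self,
        group: str,
        groups: Mapping[str, str],
        kept_samples: Optional[set[str]] = None,
    ) -> set[tuple[str, str, int, int, str]]:
        """Planted loci that a perfect pipeline reports as group-specific:
        singleton and recurrent-case entries of that group's kept samples,
        keyed by (sample, chromosome, start, end, type)."""
        out = set()
        for t in self.cnvs:
            if t.cnv_class not in (CLASS_SINGLETON, CLASS_RECURRENT_CASE):
                continue
            if groups.get(t.sample_id) != group:
                continue
            if kept_samples is not None and t.sample_id not in kept_samples:
                continue
            out.add(
                (
                    t.sample_id,
                    t.interval.chromosome,
                    t.interval.start,
                    t.interval.end,
                    t.cnv_type.value,
                )
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "locus_id": t.locus_id,
                    "sample_id": t.sample_id,
                    "chrom": t.interval.chromosome,
                    "start": t.interval.start,
                    "end": t.interval.end,
                    "type": t.cnv_type.value,
                    "cn": t.copy_number,
                    "class": t.cnv_class,
                }
                for t in self.cnvs
            ]
        )


@dataclass
class SimulationBundle:
    config: SimulationConfig
    annotation: GenomeAnnotation
    manifest: ProbeManifest
    reference_sets: dict[str, ReferenceVariantSet]
    samples: list[SampleRecord]
    signals: dict[str, SampleSignals]
    callsets: dict[str, list[CnvCall]]
    ledger: TruthLedger


# ---------------------------------------------------------------------------
# genome scaffold


def make_genome(config: SimulationConfig, rng: np.random.Generator) -> tuple[GenomeAnnotation, ProbeManifest]:
    """Deterministic genome scaffold: chromosome sizes, mid-chromosome
    centromeres, terminal telomeres, a windowed GC track (a configurable
    fraction of windows above 0.70 so the GC filter is exercised), gene
    models and an evenly spaced probe manifest."""
    lengths = {c: int(L) for c, L in config.chromosome_lengths.items()}
    centromeres = {}
    telomeres = {}
    gc_track = {}
    probe_ids: list[str] = []
    probe_chroms: list[str] = []
    probe_pos: list[int] = []
    for chrom in sorted(lengths, key=chromosome_rank):
        L = lengths[chrom]
        mid = L // 2
        centromeres[chrom] = GenomicInterval(
            chrom, mid - config.centromere_bp // 2, mid + config.centromere_bp // 2
        )
        telomeres[chrom] = [
            GenomicInterval(chrom, 0, config.telomere_bp),
            GenomicInterval(chrom, L - config.telomere_bp, L),
        ]
        n_win = int(np.ceil(L / config.gc_window_bp))
        starts = np.arange(n_win, dtype=np.int64) * config.gc_window_bp
        ends = np.minimum(starts + config.gc_window_bp, L)
        gc = np.clip(rng.normal(config.gc_mean, config.gc_sd, size=n_win), 0.25, 0.68)
        high = rng.random(n_win) < config.high_gc_rate
        gc[high] = rng.uniform(0.72, 0.80, size=int(high.sum()))
        gc_track[chrom] = (starts, ends, np.round(gc, 4))
        pos = np.arange(config.probe_spacing_bp // 2, L, config.probe_spacing_bp)
        for i, p in enumerate(pos):
            probe_ids.append(f"P_{chrom}_{i:06d}")
            probe_chroms.append(chrom)
            probe_pos.append(int(p))
    genes = []
    chrom_names = sorted(lengths, key=chromosome_rank)
    weights = np.array([lengths[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    glo, ghi = config.gene_length_range_bp
    for i in range(config.n_genes):
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=weights))]
        glen = int(rng.integers(glo, ghi + 1))
        start = int(rng.integers(0, max(1, lengths[chrom] - glen)))
        genes.append(
            GeneModel(
                gene_id=f"GENE{i + 1:04d}",
                symbol=f"GENE{i + 1:04d}",
                interval=GenomicInterval(chrom, start, start + glen),
            )
        )
    annotation = GenomeAnnotation(
        chromosome_lengths=lengths,
        centromeres=centromeres,
        telomeres=telomeres,
        gc_track=gc_track,
        genes=genes,
    )
    manifest = ProbeManifest(probe_ids, probe_chroms, probe_pos)
    return annotation, manifest


# ---------------------------------------------------------------------------
# placement of planted loci


class _Placer:
    """Rejection sampler for locus placement in callable autosomal space.

    Placed loci keep ``gap_bp`` clear of each other, of centromeres and
    telomeres, avoid high-GC windows over their gap-padded span, and retain
    at least ``min_core_probes`` probes even after the worst-case breakpoint
    jitter shrinks them, so that planted loci survive the pipeline's
    interval filters by construction.
    """

    def __init__(
        self,
        annotation: GenomeAnnotation,
        manifest: ProbeManifest,
        config: SimulationConfig,
        rng: np.random.Generator,
        min_core_probes: int = 5,
        core_shrink: float = 0.12,
    ):
        self.annotation = annotation
        self.manifest = manifest
        self.gap = config.locus_gap_bp
        self.rng = rng
        self.min_core_probes = min_core_probes
        self.core_shrink = core_shrink
        self.max_gc = 0.70
        self.chroms = [
            c for c in sorted(annotation.chromosome_lengths, key=chromosome_rank)
            if c in AUTOSOMES
        ]
        if not self.chroms:
            raise ValueError("no autosomes in the simulated genome")
        w = np.array([annotation.chromosome_lengths[c] for c in self.chroms], float)
        self.weights = w / w.sum()
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in self.chroms}

    def clashes(self, chrom: str, start: int, end: int) -> bool:
        """True when [start, end) comes within ``gap`` of a registered locus.

        Registered loci are pairwise disjoint, so within the sorted list
        both starts and ends are increasing and the rightmost entry
        starting before ``end + gap`` suffices to decide.
        """
        occ = self.occupied.get(chrom)
        if not occ:
            return False
        hi = bisect_left(occ, (end + self.gap, -1))
        return hi >= 1 and occ[hi - 1][1] > start - self.gap

    def _acceptable(self, chrom: str, start: int, end: int) -> bool:
        padded = GenomicInterval(chrom, max(0, start - self.gap), end + self.gap)
        if self.annotation.centrotelo_gap(padded) == 0:
            return False
        gc_entry = self.annotation.gc_windows(chrom)
        starts, ends, gc = gc_entry
        lo = int(np.searchsorted(ends, padded.start, side="right"))
        hi = int(np.searchsorted(starts, padded.end, side="left"))
        if np.any(gc[lo:hi] > self.max_gc):
            return False
        shrink = int(self.core_shrink * (end - start))
        core = GenomicInterval(chrom, start + shrink, end - shrink)
        if self.manifest.count_in(core) < self.min_core_probes:
            return False
        return True

    def place(self, length: int, max_tries: int = 2000) -> GenomicInterval:
        for _ in range(max_tries):
            chrom = self.chroms[int(self.rng.choice(len(self.chroms), p=self.weights))]
            L = self.annotation.chromosome_lengths[chrom]
            start = int(self.rng.integers(self.gap, max(self.gap + 1, L - length - self.gap)))
            end = start + length
            if self.clashes(chrom, start, end):
                continue
            if not self._acceptable(chrom, start, end):
                continue
            insort(self.occupied[chrom], (start, end))
            return GenomicInterval(chrom, start, end)
        raise RuntimeError(
            "could not place locus after max retries; enlarge the genome or "
            "reduce the number of planted loci"
        )


def _draw_type_cn(rng: np.random.Generator, loss_fraction: float) -> tuple[CnvType, int]:
    if rng.random() < loss_fraction:
        return CnvType.LOSS, 1
    return CnvType.GAIN, 3


def _draw_length(rng: np.random.Generator, config: SimulationConfig) -> int:
    lo, hi = config.cnv_length_range_bp
    return int(rng.integers(lo, hi + 1))


# ---------------------------------------------------------------------------
# cohort


def _draw_echo(
    rng: np.random.Generator, want_lvh: bool, sex: str, thresholds: LvhThresholds
) -> EchoMeasurements:
    """Rejection-sample echo measurements until the classification matches
    the target (closed loop with the phenotype module)."""
    for _ in range(1000):
        if want_lvh:
            echo = EchoMeasurements(
                lvidd=max(3.0, rng.normal(5.6, 0.25)),
                pwtd=max(0.6, rng.normal(1.45, 0.08)),
                ivstd=max(0.6, rng.normal(1.45, 0.08)),
                height=float(np.clip(rng.normal(1.60, 0.06), 1.40, 1.90)),
            )
        else:
            echo = EchoMeasurements(
                lvidd=max(3.0, rng.normal(4.9, 0.25)),
                pwtd=max(0.5, rng.normal(0.88, 0.07)),
                ivstd=max(0.5, rng.normal(0.92, 0.08)),
                height=float(np.clip(rng.normal(1.62, 0.07), 1.40, 1.95)),
            )
        lvmi = compute_lvmi(compute_lv_mass(echo), echo.height)
        if classify_lvh(lvmi, sex, thresholds) == want_lvh:
            return echo
    raise RuntimeError("could not draw echo measurements matching the target")


def make_cohort(
    config: SimulationConfig,
    rng: np.random.Generator,
    thresholds: LvhThresholds = LvhThresholds(),
) -> tuple[list[SampleRecord], dict[str, bool]]:
    """Cases (hypertensive with LVH) and controls (hypertensive without),
    with echo parameters drawn so the phenotype classifier reproduces the
    intended status except at ``phenotype_error_rate``."""
    samples: list[SampleRecord] = []
    phenotypes: dict[str, bool] = {}
    group_plans = [
        (GROUP_CASE, config.n_case, config.p_male_case, "CASE", (53.8, 7.5), (28.1, 3.5), (155.6, 15.0), (93.2, 10.0)),
        (GROUP_CONTROL, config.n_control, config.p_male_control, "CTRL", (52.8, 7.5), (26.2, 3.5), (149.9, 15.0), (94.5, 10.0)),
    ]
    for group, n, p_male, prefix, age_d, bmi_d, sbp_d, dbp_d in group_plans:
        for i in range(n):
            sample_id = f"{prefix}_{i + 1:03d}"
            sex = SEX_MALE if rng.random() < p_male else SEX_FEMALE
            is_case = group == GROUP_CASE
            want_lvh = is_case
            if rng.random() < config.phenotype_error_rate:
                want_lvh = not want_lvh
            echo = _draw_echo(rng, want_lvh, sex, thresholds)
            samples.append(
                SampleRecord(
                    sample_id=sample_id,
                    group=group,
                    sex=sex,
                    age=float(np.clip(rng.normal(*age_d), 30, 80)),
                    bmi=float(np.clip(rng.normal(*bmi_d), 17, 45)),
                    sbp=float(np.clip(rng.normal(*sbp_d), 110, 220)),
                    dbp=float(np.clip(rng.normal(*dbp_d), 60, 130)),
                    echo=echo,
                )
            )
            phenotypes[sample_id] = want_lvh
    return samples, phenotypes


# ---------------------------------------------------------------------------
# planted CNVs


def plant_cnvs(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    manifest: ProbeManifest,
    samples: Sequence[SampleRecord],
    rng: np.random.Generator,
) -> tuple[list[TruthCnv], _Placer]:
    """Plant the CNV landscape and return truth entries plus the placer
    (whose occupied map is reused to keep decoys and false positives away
    from planted loci)."""
    placer = _Placer(annotation, manifest, config, rng)
    cases = [s.sample_id for s in samples if s.group == GROUP_CASE]
    controls = [s.sample_id for s in samples if s.group == GROUP_CONTROL]
    all_ids = [s.sample_id for s in samples]
    truth: list[TruthCnv] = []

    # common copy-number polymorphisms: per-sample binomial carrier draws
    for k in range(config.n_cnp_loci):
        locus = placer.place(_draw_length(rng, config))
        cnv_type, cn = _draw_type_cn(rng, config.loss_fraction)
        freq = float(rng.uniform(*config.cnp_frequency_range))
        locus_id = f"CNP{k + 1:03d}|{freq:.4f}"
        carriers = [s for s in all_ids if rng.random() < freq]
        for s in carriers:
            truth.append(TruthCnv(locus_id, s, locus, cnv_type, cn, CLASS_CNP))

    # rare loci shared by one case and one control (never group-specific)
    for k in range(config.n_shared_rare_loci):
        locus = placer.place(_draw_length(rng, config))
        cnv_type, cn = _draw_type_cn(rng, config.loss_fraction)
        locus_id = f"SHR{k + 1:03d}"
        for s in (cases[k % len(cases)], controls[k % len(controls)]):
            truth.append(TruthCnv(locus_id, s, locus, cnv_type, cn, CLASS_SHARED_RARE))

    # per-genome singletons
    n_singleton = 0
    for s in samples:
        rate = (
            config.case_singleton_rate
            if s.group == GROUP_CASE
            else config.control_singleton_rate
        )
        for _ in range(int(rng.poisson(rate))):
            locus = placer.place(_draw_length(rng, config))
            cnv_type, cn = _draw_type_cn(rng, config.loss_fraction)
            n_singleton += 1
            truth.append(
                TruthCnv(f"SGL{n_singleton:04d}", s.sample_id, locus, cnv_type, cn, CLASS_SINGLETON)
            )

    # recurrent case-only loci with fixed carrier counts
    for k, n_carriers in enumerate(config.recurrent_case_carriers):
        if n_carriers > len(cases):
            raise ValueError("recurrent locus needs more carriers than cases exist")
        locus = placer.place(_draw_length(rng, config))
        cnv_type, cn = _draw_type_cn(rng, config.loss_fraction)
        carrier_ids = rng.choice(len(cases), size=n_carriers, replace=False)
        for ci in sorted(int(i) for i in carrier_ids):
            truth.append(
                TruthCnv(f"REC{k + 1:02d}", cases[ci], locus, cnv_type, cn, CLASS_RECURRENT_CASE)
            )
    return truth, placer


def make_reference_sets(
    config: SimulationConfig,
    truth: Sequence[TruthCnv],
    placer: _Placer,
    rng: np.random.Generator,
) -> dict[str, ReferenceVariantSet]:
    """DGV-like, HapMap3-like and SGVP-like sets.

    Every planted CNP locus appears in the DGV-like set (and a subset in
    the population sets) with its true frequency; decoy variants not
    planted in any genome are added in free space so they can never
    shadow a planted rare locus.
    """
    cnp_loci: dict[str, TruthCnv] = {}
    for t in truth:
        if t.cnv_class == CLASS_CNP and t.locus_id not in cnp_loci:
            cnp_loci[t.locus_id] = t
    dgv, hapmap, sgvp = [], [], []
    for i, (locus_id, t) in enumerate(sorted(cnp_loci.items())):
        freq = float(locus_id.split("|")[1])
        v = ReferenceVariant(locus_id.split("|")[0], t.interval, t.cnv_type, freq)
        dgv.append(v)
        if i % 2 == 0:
            hapmap.append(v)
        if i % 3 == 0:
            sgvp.append(v)
    for i in range(config.n_decoy_reference):
        locus = placer.place(_draw_length(rng, config))
        cnv_type, _ = _draw_type_cn(rng, config.loss_fraction)
        freq = float(rng.uniform(0.0, 0.30))
        v = ReferenceVariant(f"DECOY{i + 1:03d}", locus, cnv_type, freq)
        target = (dgv, hapmap, sgvp)[i % 3]
        target.append(v)
    return {
        "DGV": ReferenceVariantSet("DGV", dgv),
        "HapMap3": ReferenceVariantSet("HapMap3", hapmap),
        "SGVP": ReferenceVariantSet("SGVP", sgvp),
    }


# ---------------------------------------------------------------------------
# emulated calling algorithms


def _algorithm_params(config: SimulationConfig) -> dict[str, float]:
    if isinstance(config.sensitivity, Mapping):  # pragma: no cover - config sugar
        return dict(config.sensitivity)
    return {a: float(config.sensitivity) for a in config.algorithms}


def emulate_algorithm_calls(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    manifest: ProbeManifest,
    truth: Sequence[TruthCnv],
    samples: Sequence[SampleRecord],
    placer: _Placer,
    rng: np.random.Generator,
) -> tuple[dict[str, list[CnvCall]], list[EmittedCall]]:
    """Per-algorithm call sets: each true CNV is emitted with the
    algorithm's sensitivity and jittered breakpoints; Poisson false
    positives per genome are placed away from every planted locus."""
    sens = _algorithm_params(config)
    jitter = config.breakpoint_jitter
    callsets: dict[str, list[CnvCall]] = {a: [] for a in config.algorithms}
    emitted: list[EmittedCall] = []
    fp_chroms = sorted(annotation.chromosome_lengths, key=chromosome_rank)
    fp_w = np.array([annotation.chromosome_lengths[c] for c in fp_chroms], float)
    fp_w /= fp_w.sum()

    def fp_interval() -> GenomicInterval:
        for _ in range(500):
            chrom = fp_chroms[int(rng.choice(len(fp_chroms), p=fp_w))]
            L = annotation.chromosome_lengths[chrom]
            length = _draw_length(rng, config)
            start = int(rng.integers(0, max(1, L - length)))
            end = start + length
            if chrom in placer.occupied and placer.clashes(chrom, start, end):
                continue
            return GenomicInterval(chrom, start, end)
        raise RuntimeError("could not place false positive away from true loci")

    sample_order = [s.sample_id for s in samples]
    truth_by_sample: dict[str, list[TruthCnv]] = {s: [] for s in sample_order}
    for t in truth:
        truth_by_sample[t.sample_id].append(t)

    for algo in config.algorithms:
        s_algo = sens[algo]
        for sample_id in sample_order:
            for t in truth_by_sample[sample_id]:
                if rng.random() >= s_algo:
                    continue
                iv = t.interval
                if jitter > 0:
                    span = jitter * iv.length
                    L = annotation.chromosome_lengths[iv.chromosome]
                    start = int(np.clip(iv.start + rng.uniform(-span, span), 0, L - 2))
                    end = int(np.clip(iv.end + rng.uniform(-span, span), start + 1, L))
                    iv = GenomicInterval(iv.chromosome, start, end)
                call = CnvCall(
                    sample_id=sample_id,
                    interval=iv,
                    cnv_type=t.cnv_type,
                    copy_number=t.copy_number,
                    probe_count=manifest.count_in(iv),
                    algorithm=algo,
                )
                callsets[algo].append(call)
                emitted.append(
                    EmittedCall(algo, sample_id, iv, t.cnv_type, ORIGIN_TRUE, t.locus_id)
                )
            for _ in range(int(rng.poisson(config.fp_per_genome))):
                iv = fp_interval()
                cnv_type, cn = _draw_type_cn(rng, config.loss_fraction)
                callsets[algo].append(
                    CnvCall(
                        sample_id=sample_id,
                        interval=iv,
                        cnv_type=cnv_type,
                        copy_number=cn,
                        probe_count=manifest.count_in(iv),
                        algorithm=algo,
                    )
                )
                emitted.append(
                    EmittedCall(algo, sample_id, iv, cnv_type, ORIGIN_FALSE, None)
                )
    for a in callsets:
        callsets[a].sort(key=lambda c: c.sort_key())
    return callsets, emitted


# ---------------------------------------------------------------------------
# QC signals


_FAILURE_MODES = (
    QcFailure.CALL_RATE,
    QcFailure.LRR_SD,
    QcFailure.BAF_SD,
    QcFailure.BATCH_RATIO_SD,
)


def make_qc_signals(
    config: SimulationConfig,
    samples: Sequence[SampleRecord],
    rng: np.random.Generator,
) -> tuple[dict[str, SampleSignals], dict[str, tuple[str, ...]]]:
    """Per-sample LRR/BAF/call/ratio vectors over ``qc_probe_count``
    autosomal probes, with failure injections at ``qc_failure_rate``.

    A clean sample has call rate ~0.995-0.999, LRR SD 0.10-0.20,
    heterozygous-band BAF SD 0.02-0.04 and ratio SD 0.05-0.15 — all well
    inside the exclusion thresholds. Injected failures push exactly the
    chosen metric over its bound (an injected BAF failure scatters BAF
    uniformly, whose in-band SD approaches the 0.144 uniform ceiling).
    """
    n = config.qc_probe_count
    if n < 1000:
        raise ValueError("qc_probe_count must be >= 1000")
    probe_effect = rng.normal(1.0, 0.05, size=n)  # shared per-probe ratio profile
    signals: dict[str, SampleSignals] = {}
    failures: dict[str, tuple[str, ...]] = {}
    for s in samples:
        modes: tuple[str, ...] = ()
        if rng.random() < config.qc_failure_rate:
            k = 1 + int(rng.random() < 0.2)  # occasionally fail two metrics
            picked = rng.choice(len(_FAILURE_MODES), size=k, replace=False)
            modes = tuple(_FAILURE_MODES[int(i)].value for i in sorted(picked))
        call_rate = float(rng.uniform(0.995, 0.999))
        lrr_sd = float(rng.uniform(0.10, 0.20))
        baf_het_sd = float(rng.uniform(0.02, 0.04))
        ratio_sd = float(rng.uniform(0.05, 0.15))
        baf_uniform = False
        if QcFailure.CALL_RATE.value in modes:
            call_rate = float(rng.uniform(0.95, 0.985))
        if QcFailure.LRR_SD.value in modes:
            lrr_sd = float(rng.uniform(0.45, 0.60))
        if QcFailure.BAF_SD.value in modes:
            baf_uniform = True
        if QcFailure.BATCH_RATIO_SD.value in modes:
            ratio_sd = float(rng.uniform(0.35, 0.50))
        lrr = rng.normal(0.0, lrr_sd, size=n)
        genotype = rng.random(n)
        baf = np.empty(n)
        hom_a = genotype < 0.35
        hom_b = genotype > 0.65
        het = ~(hom_a | hom_b)
        baf[hom_a] = np.abs(rng.normal(0.0, 0.01, size=int(hom_a.sum())))
        baf[hom_b] = 1.0 - np.abs(rng.normal(0.0, 0.01, size=int(hom_b.sum())))
        baf[het] = np.clip(rng.normal(0.5, baf_het_sd, size=int(het.sum())), 0.0, 1.0)
        if baf_uniform:
            baf = rng.uniform(0.0, 1.0, size=n)
        called = rng.random(n) < call_rate
        ratio = probe_effect * rng.normal(1.0, ratio_sd, size=n)
        signals[s.sample_id] = SampleSignals(
            lrr=lrr, baf=baf, called=called, intensity_ratio=ratio
        )
        if modes:
            failures[s.sample_id] = modes
    return signals, failures


# ---------------------------------------------------------------------------
# top-level


def simulate(config: SimulationConfig) -> SimulationBundle:
    """Generate the complete input bundle plus the truth ledger."""
    rng = np.random.default_rng(config.seed)
    annotation, manifest = make_genome(config, rng)
    samples, phenotypes = make_cohort(config, rng)
    truth, placer = plant_cnvs(config, annotation, manifest, samples, rng)
    reference_sets = make_reference_sets(config, truth, placer, rng)
    callsets, emitted = emulate_algorithm_calls(
        config, annotation, manifest, truth, samples, placer, rng
    )
    signals, qc_failures = make_qc_signals(config, samples, rng)
    ledger = TruthLedger(
        cnvs=list(truth),
        emitted=emitted,
        qc_failures=qc_failures,
        phenotypes=phenotypes,
    )
    return SimulationBundle(
        config=config,
        annotation=annotation,
        manifest=manifest,
        reference_sets=reference_sets,
        samples=samples,
        signals=signals,
        callsets=callsets,
        ledger=ledger,
    )
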