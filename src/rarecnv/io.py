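"""Readers and writers for the tabular genomic formats the pipeline touches.

Disk conventions, converted at this boundary only:

* rawcnv call files and DGV-style reference tables, probe manifests:
  1-based inclusive coordinates/positions;
* BED-flavoured files (generic call TSV, gene models, GC track,
  centromere/telomere intervals): 0-based half-open.

Everything internal is 0-based half-open (see :mod:`rarecnv.model`).
"""
from __future__ import annotations

import csv
import logging
import math
import re
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    CnvCall,
    CnvType,
    ConsensusCnv,
    EchoMeasurements,
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    ProbeManifest,
    ReferenceVariant,
    ReferenceVariantSet,
    SampleRecord,
    chromosome_rank,
    normalize_chromosome,
)
from .qc import QcDecision, QcFailure, QcMetrics, SampleSignals

logger = logging.getLogger(__name__)

_RAWCNV_REGION = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


class DataError(ValueError):
    """A malformed or inconsistent input file."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing mandatory column '{missing[0]}'")


# ---------------------------------------------------------------------------
# CNV call files


def _parse_rawcnv_line(line: str, lineno: int, algorithm: str) -> CnvCall:
    tokens = line.split()
    if len(tokens) < 5:
        raise DataError(f"line {lineno}: expected >= 5 whitespace-separated fields")
    m = _RAWCNV_REGION.match(tokens[0])
    if not m:
        raise DataError(f"line {lineno}: unparseable region field {tokens[0]!r}")
    chrom = normalize_chromosome(m.group("chrom"))  # may raise ValueError
    start1 = int(m.group("start"))
    end1 = int(m.group("end"))
    fields: dict[str, str] = {}
    positional: list[str] = []
    for tok in tokens[1:]:
        if tok.startswith("state") and ",cn=" in tok:
            state, cn_part = tok.split(",", 1)
            fields["state"] = state
            fields["cn"] = cn_part.split("=", 1)[1]
        elif "=" in tok:
            # values may contain thousands separators (length=4,445)
            k, v = tok.split("=", 1)
            fields[k] = v
        else:
            positional.append(tok)
    try:
        numsnp = int(fields["numsnp"].replace(",", ""))
        cn = int(fields["cn"])
    except KeyError as e:
        raise DataError(f"line {lineno}: missing mandatory field {e.args[0]}") from e
    except ValueError as e:
        raise DataError(f"line {lineno}: unparseable numeric field ({e})") from e
    sample = None
    for tok in positional:
        if not tok.startswith("state"):
            sample = tok
            break
    if sample is None:
        raise DataError(f"line {lineno}: missing sample field")
    confidence = float(fields["conf"]) if "conf" in fields else None
    return CnvCall(
        sample_id=sample,
        interval=GenomicInterval(chrom, start1 - 1, end1),
        cnv_type=CnvType.from_copy_number(cn),
        copy_number=cn,
        probe_count=numsnp,
        algorithm=algorithm,
        confidence=confidence,
    )


def read_calls(path, dialect: str, algorithm: str = "") -> list[CnvCall]:
    """Read CNV calls from a rawcnv or generic TSV file.

    Lines with chromosome labels outside the canonical set are skipped and
    counted in the log (record-level errors); an unparseable mandatory
    field raises :class:`DataError` naming the line.
    """
    path = Path(path)
    if dialect == "rawcnv":
        calls: list[CnvCall] = []
        n_bad_chrom = 0
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                try:
                    calls.append(_parse_rawcnv_line(line, lineno, algorithm))
                except DataError:
                    raise
                except ValueError:
                    n_bad_chrom += 1
        if n_bad_chrom:
            logger.warning("%s: skipped %d lines with unknown chromosome", path, n_bad_chrom)
        return calls
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        if df.empty and df.columns.size == 0:
            return []
        _require_columns(df, ["sample_id", "chrom", "start", "end", "type"], path)
        calls = []
        n_bad_chrom = 0
        for i, row in enumerate(df.itertuples(index=False), start=2):
            try:
                chrom = normalize_chromosome(row.chrom)
            except ValueError:
                n_bad_chrom += 1
                continue
            cn = getattr(row, "cn", None)
            cn = None if cn is None or (isinstance(cn, float) and math.isnan(cn)) else int(cn)
            probes = getattr(row, "probes", 0)
            probes = 0 if probes is None or (isinstance(probes, float) and math.isnan(probes)) else int(probes)
            conf = getattr(row, "confidence", None)
            conf = None if conf is None or (isinstance(conf, float) and math.isnan(conf)) else float(conf)
            algo = getattr(row, "algorithm", algorithm)
            if algo is None or (isinstance(algo, float) and math.isnan(algo)):
                algo = algorithm
            try:
                calls.append(
                    CnvCall(
                        sample_id=str(row.sample_id),
                        interval=GenomicInterval(chrom, int(row.start), int(row.end)),
                        cnv_type=CnvType.parse(row.type),
                        copy_number=cn,
                        probe_count=probes,
                        algorithm=str(algo),
                        confidence=conf,
                    )
                )
            except ValueError as e:
                raise DataError(f"{path}: line {i}: {e}") from e
        if n_bad_chrom:
            logger.warning("%s: skipped %d rows with unknown chromosome", path, n_bad_chrom)
        return calls
    raise DataError(f"unknown call dialect: {dialect!r}")


def _sorted_calls(calls: Iterable[CnvCall]) -> list[CnvCall]:
    return sorted(
        calls,
        key=lambda c: (
            chromosome_rank(c.interval.chromosome),
            c.interval.start,
            c.sample_id,
            c.algorithm,
            c.interval.end,
        ),
    )


def write_calls(calls: Iterable[CnvCall], path, dialect: str) -> None:
    """Write calls sorted by (chromosome, start, sample_id).

    rawcnv uses 1-based inclusive coordinates and requires copy_number;
    the generic TSV is BED-flavoured 0-based half-open.
    """
    path = Path(path)
    calls = _sorted_calls(calls)
    if dialect == "rawcnv":
        state_by_cn = {0: "state1", 1: "state2", 3: "state5", 4: "state6"}
        with open(path, "w") as fh:
            for c in calls:
                if c.copy_number is None:
                    raise DataError(
                        "rawcnv dialect requires copy_number on every call"
                    )
                iv = c.interval
                state = state_by_cn.get(c.copy_number, "state6")
                length = f"{iv.length:,}"
                conf = f" conf={c.confidence:g}" if c.confidence is not None else ""
                fh.write(
                    f"{iv.chromosome}:{iv.start + 1}-{iv.end} "
                    f"numsnp={c.probe_count} length={length} "
                    f"{state},cn={c.copy_number} {c.sample_id} "
                    f"startsnp=. endsnp=.{conf}\n"
                )
        return
    if dialect == "tsv":
        rows = [
            {
                "sample_id": c.sample_id,
                "chrom": c.interval.chromosome,
                "start": c.interval.start,
                "end": c.interval.end,
                "type": c.cnv_type.value,
                "cn": "" if c.copy_number is None else c.copy_number,
                "probes": c.probe_count,
                "algorithm": c.algorithm,
                "confidence": "" if c.confidence is None else repr(c.confidence),
            }
            for c in calls
        ]
        pd.DataFrame(
            rows,
            columns=[
                "sample_id", "chrom", "start", "end", "type",
                "cn", "probes", "algorithm", "confidence",
            ],
        ).to_csv(path, sep="\t", index=False)
        return
    raise DataError(f"unknown call dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# Reference variant sets (DGV-style, 1-based inclusive on disk)


def read_reference_set(path, name: Optional[str] = None) -> ReferenceVariantSet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, ["variant_id", "chrom", "start", "end"], path)
    variants = []
    for row in df.itertuples(index=False):
        t = getattr(row, "type", None)
        if t is None or (isinstance(t, float) and math.isnan(t)) or str(t).lower() in ("any", ""):
            cnv_type = None
        else:
            cnv_type = CnvType.parse(t)
        freq = getattr(row, "frequency", None)
        freq = None if freq is None or (isinstance(freq, float) and math.isnan(freq)) else float(freq)
        variants.append(
            ReferenceVariant(
                variant_id=str(row.variant_id),
                interval=GenomicInterval(
                    normalize_chromosome(row.chrom), int(row.start) - 1, int(row.end)
                ),
                cnv_type=cnv_type,
                frequency=freq,
            )
        )
    return ReferenceVariantSet(name or path.stem, variants)


def write_reference_set(refset: ReferenceVariantSet, path) -> None:
    rows = [
        {
            "variant_id": v.variant_id,
            "chrom": v.interval.chromosome,
            "start": v.interval.start + 1,
            "end": v.interval.end,
            "type": "any" if v.cnv_type is None else v.cnv_type.value,
            "frequency": "" if v.frequency is None else repr(v.frequency),
        }
        for v in refset.variants
    ]
    pd.DataFrame(
        rows, columns=["variant_id", "chrom", "start", "end", "type", "frequency"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Probe manifest (1-based positions on disk)


def read_manifest(path) -> ProbeManifest:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, ["probe_id", "chrom", "position"], path)
    try:
        return ProbeManifest(
            probe_ids=[str(p) for p in df["probe_id"]],
            chromosomes=[normalize_chromosome(c) for c in df["chrom"]],
            positions=[int(p) - 1 for p in df["position"]],
        )
    except ValueError as e:
        raise DataError(f"{path}: {e}") from e


def write_manifest(manifest: ProbeManifest, path) -> None:
    rows = [
        {"probe_id": pid, "chrom": chrom, "position": pos + 1}
        for pid, chrom, pos in manifest.records()
    ]
    pd.DataFrame(rows, columns=["probe_id", "chrom", "position"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Genome annotation (directory of BED-flavoured tables)

CHROMS_FILE = "chromosomes.tsv"
CENTROTELO_FILE = "centromeres_telomeres.tsv"
GC_FILE = "gc_track.tsv"
GENES_FILE = "genes.bed"


def write_annotation(annotation: GenomeAnnotation, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    chroms = sorted(annotation.chromosome_lengths, key=chromosome_rank)
    pd.DataFrame(
        [{"chrom": c, "length": annotation.chromosome_lengths[c]} for c in chroms]
    ).to_csv(directory / CHROMS_FILE, sep="\t", index=False)
    rows = []
    for c in chroms:
        cen = annotation.centromeres.get(c)
        if cen is not None:
            rows.append({"chrom": c, "start": cen.start, "end": cen.end, "kind": "centromere"})
        for t in annotation.telomeres.get(c, ()):
            rows.append({"chrom": c, "start": t.start, "end": t.end, "kind": "telomere"})
    pd.DataFrame(rows, columns=["chrom", "start", "end", "kind"]).to_csv(
        directory / CENTROTELO_FILE, sep="\t", index=False
    )
    gc_rows = []
    for c in chroms:
        if not annotation.has_gc_track:
            break
        try:
            starts, ends, gc = annotation.gc_windows(c)
        except KeyError:
            continue
        for s, e, g in zip(starts, ends, gc):
            gc_rows.append({"chrom": c, "start": int(s), "end": int(e), "gc": f"{g:.4f}"})
    pd.DataFrame(gc_rows, columns=["chrom", "start", "end", "gc"]).to_csv(
        directory / GC_FILE, sep="\t", index=False
    )
    with open(directory / GENES_FILE, "w") as fh:
        for g in annotation.genes:
            iv = g.interval
            fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{g.symbol}\n")


def read_annotation(directory) -> GenomeAnnotation:
    directory = Path(directory)
    chroms_df = pd.read_csv(directory / CHROMS_FILE, sep="\t", dtype={"chrom": str})
    _require_columns(chroms_df, ["chrom", "length"], directory / CHROMS_FILE)
    lengths = {
        normalize_chromosome(r.chrom): int(r.length) for r in chroms_df.itertuples()
    }
    centromeres: dict[str, GenomicInterval] = {}
    telomeres: dict[str, list[GenomicInterval]] = {}
    ct_path = directory / CENTROTELO_FILE
    if ct_path.exists():
        ct = pd.read_csv(ct_path, sep="\t", dtype={"chrom": str})
        if not ct.empty:
            _require_columns(ct, ["chrom", "start", "end", "kind"], ct_path)
            for r in ct.itertuples():
                iv = GenomicInterval(normalize_chromosome(r.chrom), int(r.start), int(r.end))
                if r.kind == "centromere":
                    centromeres[iv.chromosome] = iv
                else:
                    telomeres.setdefault(iv.chromosome, []).append(iv)
    gc_track = {}
    gc_path = directory / GC_FILE
    if gc_path.exists():
        gc = pd.read_csv(gc_path, sep="\t", dtype={"chrom": str})
        if not gc.empty:
            _require_columns(gc, ["chrom", "start", "end", "gc"], gc_path)
            for chrom, sub in gc.groupby("chrom", sort=False):
                gc_track[normalize_chromosome(chrom)] = (
                    sub["start"].to_numpy(dtype=np.int64),
                    sub["end"].to_numpy(dtype=np.int64),
                    sub["gc"].to_numpy(dtype=float),
                )
    genes = []
    genes_path = directory / GENES_FILE
    if genes_path.exists():
        with open(genes_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise DataError(f"{genes_path}: line {lineno}: BED4 row expected")
                genes.append(
                    GeneModel(
                        gene_id=parts[3],
                        symbol=parts[3],
                        interval=GenomicInterval(
                            normalize_chromosome(parts[0]), int(parts[1]), int(parts[2])
                        ),
                    )
                )
    return GenomeAnnotation(
        chromosome_lengths=lengths,
        centromeres=centromeres,
        telomeres=telomeres,
        gc_track=gc_track or None,
        genes=genes,
    )


# ---------------------------------------------------------------------------
# Sample manifest (CSV)

_SAMPLE_COLUMNS = [
    "sample_id", "group", "sex", "age", "bmi", "sbp", "dbp",
    "lvidd", "pwtd", "ivstd", "height",
]


def read_samples(path) -> list[SampleRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["sample_id", "group", "sex"], path)
    samples = []
    for row in df.itertuples(index=False):
        def opt(name: str) -> Optional[float]:
            v = getattr(row, name, None)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return float(v)

        echo = None
        echo_vals = {k: opt(k) for k in ("lvidd", "pwtd", "ivstd", "height")}
        if all(v is not None for v in echo_vals.values()):
            echo = EchoMeasurements(**echo_vals)  # type: ignore[arg-type]
        samples.append(
            SampleRecord(
                sample_id=str(row.sample_id),
                group=str(row.group),
                sex=str(row.sex),
                age=opt("age"),
                bmi=opt("bmi"),
                sbp=opt("sbp"),
                dbp=opt("dbp"),
                echo=echo,
            )
        )
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise DataError(f"{path}: duplicate sample_id")
    return samples


def write_samples(samples: Iterable[SampleRecord], path) -> None:
    def fmt(v: Optional[float]) -> str:
        return "" if v is None else repr(v)  # repr round-trips float64 exactly

    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id, "group": s.group, "sex": s.sex,
            "age": fmt(s.age), "bmi": fmt(s.bmi), "sbp": fmt(s.sbp), "dbp": fmt(s.dbp),
            "lvidd": fmt(s.echo.lvidd if s.echo else None),
            "pwtd": fmt(s.echo.pwtd if s.echo else None),
            "ivstd": fmt(s.echo.ivstd if s.echo else None),
            "height": fmt(s.echo.height if s.echo else None),
        }
        rows.append(row)
    pd.DataFrame(rows, columns=_SAMPLE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# QC signals (long TSV) and QC report


def write_signals(signals: Mapping[str, SampleSignals], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tprobe_index\tlrr\tbaf\tcalled\tratio\n")
        for sample_id in signals:
            s = signals[sample_id]
            for i in range(len(s.lrr)):
                fh.write(
                    f"{sample_id}\t{i}\t{s.lrr[i]:.6g}\t{s.baf[i]:.6g}\t"
                    f"{int(s.called[i])}\t{s.intensity_ratio[i]:.6g}\n"
                )


def read_signals(path) -> dict[str, SampleSignals]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample_id", "lrr", "baf", "called", "ratio"], path)
    out = {}
    for sample_id, sub in df.groupby("sample_id", sort=False):
        out[str(sample_id)] = SampleSignals(
            lrr=sub["lrr"].to_numpy(dtype=float),
            baf=sub["baf"].to_numpy(dtype=float),
            called=sub["called"].to_numpy(dtype=bool),
            intensity_ratio=sub["ratio"].to_numpy(dtype=float),
        )
    return out


def write_qc_report(
    metrics: Sequence[QcMetrics], decisions: Sequence[QcDecision], path
) -> None:
    dec = {d.sample_id: d for d in decisions}
    rows = []
    for m in metrics:
        d = dec[m.sample_id]
        rows.append(
            {
                "sample_id": m.sample_id,
                "call_rate": repr(m.call_rate),
                "lrr_sd": repr(m.lrr_sd),
                "baf_sd": repr(m.baf_sd),
                "batch_ratio_sd": repr(m.batch_ratio_sd),
                "aggregate_cnv_length": (
                    "" if m.aggregate_cnv_length is None else m.aggregate_cnv_length
                ),
                "kept": int(d.kept),
                "reasons": ";".join(sorted(r.value for r in d.failure_reasons)) or "-",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_qc_report(path) -> tuple[list[QcMetrics], list[QcDecision]]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ["sample_id", "call_rate", "lrr_sd", "baf_sd", "batch_ratio_sd", "kept", "reasons"], path)
    metrics, decisions = [], []
    for row in df.itertuples(index=False):
        agg = getattr(row, "aggregate_cnv_length", None)
        agg = None if agg is None or (isinstance(agg, float) and math.isnan(agg)) else int(agg)
        metrics.append(
            QcMetrics(
                sample_id=str(row.sample_id),
                call_rate=float(row.call_rate),
                lrr_sd=float(row.lrr_sd),
                baf_sd=float(row.baf_sd),
                batch_ratio_sd=float(row.batch_ratio_sd),
                aggregate_cnv_length=agg,
            )
        )
        reasons = frozenset(
            QcFailure(r) for r in str(row.reasons).split(";") if r and r != "-"
        )
        decisions.append(QcDecision(str(row.sample_id), kept=bool(row.kept), failure_reasons=reasons))
    return metrics, decisions


# ---------------------------------------------------------------------------
# Consensus calls (BED-flavoured TSV with provenance columns)


def write_consensus(calls: Sequence[ConsensusCnv], path) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "chrom": c.interval.chromosome,
            "start": c.interval.start,
            "end": c.interval.end,
            "type": c.cnv_type.value,
            "probes": c.probe_count,
            "supporting_algorithms": ",".join(sorted(c.supporting_algorithms)),
            "n_algorithms": c.n_algorithms,
        }
        for c in sorted(calls, key=lambda c: c.sort_key())
    ]
    pd.DataFrame(
        rows,
        columns=[
            "sample_id", "chrom", "start", "end", "type",
            "probes", "supporting_algorithms", "n_algorithms",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_consensus(path) -> list[ConsensusCnv]:
    """Read a consensus TSV. Member-call provenance is not serialized, so
    reconstructed objects carry empty ``member_calls``."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if df.empty:
        return []
    _require_columns(
        df, ["sample_id", "chrom", "start", "end", "type", "supporting_algorithms"], path
    )
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ConsensusCnv(
                sample_id=str(row.sample_id),
                interval=GenomicInterval(
                    normalize_chromosome(row.chrom), int(row.start), int(row.end)
                ),
                cnv_type=CnvType.parse(row.type),
                supporting_algorithms=frozenset(
                    str(row.supporting_algorithms).split(",")
                ),
                probe_count=int(getattr(row, "probes", 0) or 0),
            )
        )
    return out
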