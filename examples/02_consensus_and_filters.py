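"""Multi-algorithm consensus merging and the five CNV-level filters.

Builds a handful of calls from three 'algorithms' in one sample, merges
them at 50% reciprocal overlap with >= 2-of-3 support, and shows how the
interval filters (probe count, GC, centromere/telomere distance, size,
sex chromosomes) dispose of each consensus call.
"""
import numpy as np

from rarecnv import (
    CnvCall, CnvType, GenomeAnnotation, GenomicInterval, ProbeManifest,
    annotate_probe_counts, apply_cnv_filters, merge_algorithm_calls,
)

iv = GenomicInterval
calls = [
    # the same 50 kb deletion seen by all three algorithms, breakpoints jittered
    CnvCall("S1", iv("chr1", 1_000_000, 1_050_000), CnvType.LOSS, algorithm="cnvpartition"),
    CnvCall("S1", iv("chr1", 1_004_000, 1_055_000), CnvType.LOSS, algorithm="penncnv"),
    CnvCall("S1", iv("chr1", 998_000, 1_048_000), CnvType.LOSS, algorithm="ipattern"),
    # a gain seen by two algorithms
    CnvCall("S1", iv("chr1", 3_000_000, 3_080_000), CnvType.GAIN, algorithm="penncnv"),
    CnvCall("S1", iv("chr1", 3_001_000, 3_079_000), CnvType.GAIN, algorithm="ipattern"),
    # a call seen by one algorithm only: never becomes a stringent call
    CnvCall("S1", iv("chr1", 6_000_000, 6_030_000), CnvType.LOSS, algorithm="penncnv"),
    # a chrX call supported twice, removed later by the sex-chromosome filter
    CnvCall("S1", iv("chrX", 2_000_000, 2_040_000), CnvType.LOSS, algorithm="penncnv"),
    CnvCall("S1", iv("chrX", 2_000_000, 2_040_000), CnvType.LOSS, algorithm="ipattern"),
]

consensus = merge_algorithm_calls(calls, min_support=2, link_fraction=0.5)
print(f"{len(calls)} raw calls -> {len(consensus)} stringent consensus calls (>=2 of 3 algorithms)")
for c in consensus:
    print(f"  {c.interval}  {c.cnv_type.value:4s}  support={sorted(c.supporting_algorithms)}")

# a probe every 5 kb, an annotation with a mid-chromosome centromere
positions = list(range(2_500, 10_000_000, 5_000)) + list(range(2_500, 5_000_000, 5_000))
chroms = ["chr1"] * 2000 + ["chrX"] * 1000
manifest = ProbeManifest([f"p{i}" for i in range(3000)], chroms, positions)
starts = np.arange(0, 10_000_000, 10_000, dtype=np.int64)
annotation = GenomeAnnotation(
    chromosome_lengths={"chr1": 10_000_000, "chrX": 5_000_000},
    centromeres={"chr1": GenomicInterval("chr1", 4_900_000, 5_100_000)},
    telomeres={"chr1": [GenomicInterval("chr1", 0, 10_000)]},
    gc_track={"chr1": (starts, starts + 10_000, np.full(len(starts), 0.42))},
)

consensus = annotate_probe_counts(consensus, manifest)
outcomes, tally = apply_cnv_filters(consensus, annotation)
print("\nfilter outcomes:")
for o in outcomes:
    verdict = "retained" if o.retained else f"excluded ({', '.join(r.value for r in o.exclusion_reasons)})"
    print(f"  {o.call.interval}  probes={o.call.probe_count:3d}  {verdict}")
print("\ntally (input = retained + excluded):")
print(tally.to_string(index=False))
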