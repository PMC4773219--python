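"""Reciprocal overlap, consensus merging and CNV-level filters."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import linked_oracle, overlap_bases, single_linkage_oracle
from rarecnv import (
    CnvCall,
    CnvType,
    ConsensusCnv,
    FilterParams,
    FilterReason,
    GenomeAnnotation,
    GenomicInterval,
    ProbeManifest,
    annotate_probe_counts,
    apply_cnv_filters,
    merge_algorithm_calls,
    reciprocal_overlap,
)
from rarecnv.consensus import retained_calls
from rarecnv.intervals import single_linkage_clusters

intervals_st = st.builds(
    lambda c, s, l: GenomicInterval(c, s, s + l),
    st.sampled_from(["chr1", "chr2"]),
    st.integers(0, 3000),
    st.integers(1, 800),
)


class TestReciprocalOverlap:
    def test_identical_intervals(self):
        a = GenomicInterval("chr1", 100, 200)
        r = reciprocal_overlap(a, a)
        assert (r.overlap_bp, r.fraction_a, r.fraction_b) == (100, 1.0, 1.0)

    def test_disjoint_and_cross_chromosome_are_zero(self):
        a = GenomicInterval("chr1", 0, 1000)
        assert reciprocal_overlap(a, GenomicInterval("chr1", 5000, 6000)).overlap_bp == 0
        assert reciprocal_overlap(a, GenomicInterval("chr2", 0, 1000)).overlap_bp == 0

    @given(a=intervals_st, b=intervals_st)
    def test_matches_base_counting_oracle(self, a, b):
        r = reciprocal_overlap(a, b)
        ov = overlap_bases(a, b)
        assert r.overlap_bp == ov
        assert r.fraction_a == ov / a.length
        assert r.fraction_b == ov / b.length

    @given(a=intervals_st, b=intervals_st, shift=st.integers(0, 10_000))
    def test_symmetry_and_translation_invariance(self, a, b, shift):
        r1 = reciprocal_overlap(a, b)
        r2 = reciprocal_overlap(b, a)
        assert (r1.fraction_a, r1.fraction_b) == (r2.fraction_b, r2.fraction_a)
        a2 = GenomicInterval(a.chromosome, a.start + shift, a.end + shift)
        b2 = GenomicInterval(b.chromosome, b.start + shift, b.end + shift)
        r3 = reciprocal_overlap(a2, b2)
        assert (r3.overlap_bp, r3.fraction_a, r3.fraction_b) == (
            r1.overlap_bp, r1.fraction_a, r1.fraction_b,
        )


def _random_instance(rng, n, n_samples=1, algos=("a1", "a2", "a3")):
    calls = []
    for i in range(n):
        start = int(rng.integers(0, 120))
        length = int(rng.integers(5, 60))
        calls.append(
            CnvCall(
                sample_id=f"S{int(rng.integers(0, n_samples))}",
                interval=GenomicInterval("chr1", start, start + length),
                cnv_type=CnvType.LOSS,
                algorithm=str(rng.choice(list(algos))),
            )
        )
    return calls


class TestClusteringAgainstEnumeration:
    def test_single_linkage_matches_partition_enumeration(self, rng):
        for _ in range(150):
            n = int(rng.integers(2, 9))
            ivs = []
            for _ in range(n):
                start = int(rng.integers(0, 100))
                ivs.append(GenomicInterval("chr1", start, start + int(rng.integers(5, 60))))
            got = single_linkage_clusters(list(range(n)), lambda i: ivs[i], 0.5)
            got_sets = sorted((frozenset(c) for c in got), key=lambda s: tuple(sorted(s)))
            assert got_sets == single_linkage_oracle(ivs, 0.5)

    def test_chain_linkage_is_transitive(self):
        # A~B and B~C at 50% but A and C barely overlap: one cluster of 3
        a = GenomicInterval("chr1", 0, 100)
        b = GenomicInterval("chr1", 50, 150)
        c = GenomicInterval("chr1", 100, 200)
        calls = [
            CnvCall("S", iv, CnvType.LOSS, algorithm=alg)
            for iv, alg in zip((a, b, c), ("a1", "a2", "a3"))
        ]
        (consensus,) = merge_algorithm_calls(calls, min_support=2)
        assert consensus.interval == GenomicInterval("chr1", 0, 200)
        assert consensus.supporting_algorithms == {"a1", "a2", "a3"}


class TestMerging:
    def test_identical_call_in_three_algorithms(self):
        iv = GenomicInterval("chr1", 10_000, 60_000)
        calls = [CnvCall("S1", iv, CnvType.GAIN, algorithm=a) for a in "abc"]
        (consensus,) = merge_algorithm_calls(calls)
        assert consensus.n_algorithms == 3 and consensus.interval == iv

    def test_single_algorithm_call_dropped(self):
        calls = [CnvCall("S1", GenomicInterval("chr1", 0, 1000), CnvType.LOSS, algorithm="a1")]
        assert merge_algorithm_calls(calls, min_support=2) == []

    def test_different_samples_or_types_never_merge(self):
        iv = GenomicInterval("chr1", 0, 1000)
        calls = [
            CnvCall("S1", iv, CnvType.LOSS, algorithm="a1"),
            CnvCall("S2", iv, CnvType.LOSS, algorithm="a2"),
            CnvCall("S1", iv, CnvType.GAIN, algorithm="a2"),
        ]
        assert merge_algorithm_calls(calls, min_support=2) == []

    def test_duplicate_calls_collapse(self, caplog):
        iv = GenomicInterval("chr1", 0, 1000)
        calls = [
            CnvCall("S1", iv, CnvType.LOSS, algorithm="a1"),
            CnvCall("S1", iv, CnvType.LOSS, algorithm="a1"),
            CnvCall("S1", iv, CnvType.LOSS, algorithm="a2"),
        ]
        (consensus,) = merge_algorithm_calls(calls)
        assert consensus.supporting_algorithms == {"a1", "a2"}
        assert len(consensus.member_calls) == 2

    def test_merge_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(150):
            n = int(rng.integers(2, 9))
            calls = _random_instance(rng, n, n_samples=2)
            got = {
                (c.sample_id, c.interval.start, c.interval.end, c.supporting_algorithms)
                for c in merge_algorithm_calls(calls, min_support=2)
            }
            # oracle: enumerate clusters per sample, keep >=2 algorithms, outer bounds
            expected = set()
            for sample in {c.sample_id for c in calls}:
                sub = [c for c in calls if c.sample_id == sample]
                for block in single_linkage_oracle([c.interval for c in sub], 0.5):
                    support = frozenset(sub[i].algorithm for i in block)
                    if len(support) >= 2:
                        expected.add(
                            (
                                sample,
                                min(sub[i].interval.start for i in block),
                                max(sub[i].interval.end for i in block),
                                support,
                            )
                        )
            assert got == expected

    def test_raising_min_support_never_increases_count(self, rng):
        for _ in range(30):
            calls = _random_instance(rng, 8, n_samples=2)
            n2 = len(merge_algorithm_calls(calls, min_support=2))
            n3 = len(merge_algorithm_calls(calls, min_support=3))
            assert n3 <= n2

    def test_merging_is_idempotent_on_consensus_output(self, small_noisy_bundle):
        b = small_noisy_bundle
        consensus = merge_algorithm_calls(
            [c for calls in b.callsets.values() for c in calls], min_support=2
        )
        # re-present each consensus interval once per supporting algorithm
        again = merge_algorithm_calls(
            [
                CnvCall(c.sample_id, c.interval, c.cnv_type, algorithm=a)
                for c in consensus
                for a in sorted(c.supporting_algorithms)
            ],
            min_support=2,
        )
        key = lambda c: (c.sample_id, c.interval, c.cnv_type, c.supporting_algorithms)
        assert sorted(map(key, again)) == sorted(map(key, consensus))


def _dense_manifest(spacing=200, length=1_000_000):
    pos = list(range(spacing // 2, length, spacing))
    return ProbeManifest(
        [f"p{i}" for i in range(len(pos))], ["chr1"] * len(pos), pos
    )


class TestProbeAnnotation:
    def test_exact_probe_counts(self):
        manifest = ProbeManifest(["p1", "p2", "p3", "p4", "p5"], ["chr1"] * 5, [100, 200, 300, 400, 500])
        call = ConsensusCnv(
            "S", GenomicInterval("chr1", 100, 501), CnvType.LOSS, frozenset({"a"})
        )
        (annotated,) = annotate_probe_counts([call], manifest)
        assert annotated.probe_count == 5
        between = ConsensusCnv(
            "S", GenomicInterval("chr1", 101, 200), CnvType.LOSS, frozenset({"a"})
        )
        (annotated,) = annotate_probe_counts([between], manifest)
        assert annotated.probe_count == 0

    def test_random_intervals_match_linear_scan(self, rng):
        n = 300
        chroms = list(rng.choice(["chr1", "chr2"], size=n))
        pos = [int(x) for x in rng.integers(0, 500_000, size=n)]
        manifest = ProbeManifest([f"p{i}" for i in range(n)], chroms, pos)
        for _ in range(500):
            c = str(rng.choice(["chr1", "chr2"]))
            a = int(rng.integers(0, 500_000))
            iv = GenomicInterval(c, a, a + int(rng.integers(1, 100_000)))
            call = ConsensusCnv("S", iv, CnvType.LOSS, frozenset({"x"}))
            (annotated,) = annotate_probe_counts([call], manifest)
            assert annotated.probe_count == sum(
                1 for cc, p in zip(chroms, pos) if cc == c and a <= p < iv.end
            )


def _annotation(gc_windows=None):
    gc = gc_windows or {}
    track = {}
    if gc:
        starts = np.array(sorted(gc), dtype=np.int64)
        ends = starts + 10_000
        vals = np.array([gc[s] for s in sorted(gc)], dtype=float)
        track = {"chr1": (starts, ends, vals)}
    return GenomeAnnotation(
        chromosome_lengths={"chr1": 10_000_000, "chrX": 5_000_000},
        centromeres={"chr1": GenomicInterval("chr1", 5_000_000, 5_100_000)},
        telomeres={"chr1": [GenomicInterval("chr1", 0, 10_000)]},
        gc_track=track or None,
    )


def _call(start, end, chrom="chr1", probes=10, algos=("a", "b")):
    return ConsensusCnv(
        "S", GenomicInterval(chrom, start, end), CnvType.LOSS,
        frozenset(algos), probe_count=probes,
    )


class TestFilters:
    def test_probe_count_boundary(self):
        ann = _annotation()
        outcomes, _ = apply_cnv_filters([_call(1_000_000, 1_050_000, probes=4)], ann)
        assert outcomes[0].exclusion_reasons == {FilterReason.FEW_PROBES}
        outcomes, _ = apply_cnv_filters([_call(1_000_000, 1_050_000, probes=5)], ann)
        assert outcomes[0].retained

    def test_length_boundary_at_one_kb(self):
        ann = _annotation()
        outcomes, _ = apply_cnv_filters([_call(1_000_000, 1_000_999)], ann)
        assert FilterReason.TOO_SMALL in outcomes[0].exclusion_reasons
        outcomes, _ = apply_cnv_filters([_call(1_000_000, 1_001_000)], ann)
        assert outcomes[0].retained  # exactly 1 kb is not "less than 1 kb"

    def test_gc_boundary(self):
        ann70 = _annotation({1_000_000: 0.70})
        outcomes, _ = apply_cnv_filters([_call(1_000_000, 1_010_000)], ann70)
        assert outcomes[0].retained
        ann71 = _annotation({1_000_000: 0.71})
        outcomes, _ = apply_cnv_filters([_call(1_000_000, 1_010_000)], ann71)
        assert outcomes[0].exclusion_reasons == {FilterReason.HIGH_GC}

    def test_gc_is_length_weighted_over_windows(self):
        # 10 kb at 0.75 + 30 kb at 0.68 -> mean 0.6975, retained
        ann = _annotation({1_000_000: 0.75, 1_010_000: 0.68, 1_020_000: 0.68, 1_030_000: 0.68})
        outcomes, _ = apply_cnv_filters([_call(1_000_000, 1_040_000)], ann)
        assert outcomes[0].retained

    def test_centrotelo_gap_boundary(self):
        ann = _annotation()
        # centromere starts at 5,000,000
        near = _call(5_000_000 - 29_999 - 50_000, 5_000_000 - 29_999)
        outcomes, _ = apply_cnv_filters([near], ann)
        assert outcomes[0].exclusion_reasons == {FilterReason.CENTROTELO}
        at_margin = _call(5_000_000 - 30_000 - 50_000, 5_000_000 - 30_000)
        outcomes, _ = apply_cnv_filters([at_margin], ann)
        assert outcomes[0].retained

    def test_sex_chromosome_excluded(self):
        outcomes, _ = apply_cnv_filters([_call(1_000_000, 1_050_000, chrom="chrX")], _annotation())
        assert outcomes[0].exclusion_reasons == {FilterReason.SEX_CHROM}

    def test_large_calls_flagged_not_excluded(self):
        outcomes, _ = apply_cnv_filters([_call(1_200_000, 2_900_000)], _annotation())
        assert outcomes[0].retained and outcomes[0].large_call_review

    def test_large_call_hard_cap(self):
        params = FilterParams(large_call_cap_bp=1_000_000)
        outcomes, _ = apply_cnv_filters([_call(1_200_000, 2_900_000)], _annotation(), params)
        assert outcomes[0].exclusion_reasons == {FilterReason.LARGE_CALL}

    def test_missing_gc_track_skips_rule(self, caplog):
        ann = GenomeAnnotation(chromosome_lengths={"chr1": 10_000_000})
        outcomes, _ = apply_cnv_filters([_call(1_000_000, 1_050_000)], ann)
        assert outcomes[0].retained

    def test_tally_conserves_and_counts_multireason_once(self):
        ann = _annotation({1_000_000: 0.75})
        calls = [
            _call(1_000_000, 1_000_500, probes=2),  # HIGH_GC + TOO_SMALL + FEW_PROBES
            _call(2_000_000, 2_050_000),  # clean
            _call(1_000_000, 1_050_000, chrom="chrX"),  # SEX_CHROM
        ]
        outcomes, tally = apply_cnv_filters(calls, ann)
        t = dict(zip(tally.category, tally.n))
        assert t["input"] == 3
        assert t["input"] == t["retained"] + t["excluded"]
        assert t["excluded"] == 2
        assert t["excluded_HIGH_GC"] == 1 and t["excluded_TOO_SMALL"] == 1
        assert t["excluded_FEW_PROBES"] == 1 and t["excluded_SEX_CHROM"] == 1
        assert len(retained_calls(outcomes)) == t["retained"]
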