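"""Rarity rules, case/control specificity, recurrence and burden."""
import numpy as np
import pytest

from oracles import linked_oracle, single_linkage_oracle
from rarecnv import (
    CnvType,
    ConsensusCnv,
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    ReferenceVariant,
    ReferenceVariantSet,
    annotate_genes,
    assess_rarity,
    burden_report,
    case_control_specific,
    filter_known_cnp,
    filter_reference_overlap,
    find_recurrent,
    find_singletons,
)
from rarecnv.rarity import RarityStatus, genes_to_dash, rarity_tally, study_unique_calls


def _call(sample, start, end, cnv_type=CnvType.LOSS, chrom="chr1"):
    return ConsensusCnv(
        sample, GenomicInterval(chrom, start, end), cnv_type, frozenset({"a", "b"})
    )


def _ref(vid, start, end, freq=None, cnv_type=None, chrom="chr1"):
    return ReferenceVariant(vid, GenomicInterval(chrom, start, end), cnv_type, freq)


class TestCnpRule:
    def test_single_bp_overlap_with_common_cnp_excludes(self):
        cnp = ReferenceVariantSet("DGV", [_ref("c1", 1000, 2000, freq=0.05)])
        (d,) = filter_known_cnp([_call("S", 1999, 5000)], cnp)
        assert d.status is RarityStatus.KNOWN_CNP and d.matched_reference_ids == ("c1",)

    def test_low_frequency_variant_does_not_trigger_rule(self):
        cnp = ReferenceVariantSet("DGV", [_ref("c1", 1000, 2000, freq=0.005)])
        (d,) = filter_known_cnp([_call("S", 1500, 5000)], cnp)
        assert d.status is RarityStatus.RARE

    def test_type_mismatch_does_not_trigger_when_matching_types(self):
        cnp = ReferenceVariantSet("DGV", [_ref("c1", 1000, 2000, freq=0.05, cnv_type=CnvType.GAIN)])
        (d,) = filter_known_cnp([_call("S", 1500, 5000, cnv_type=CnvType.LOSS)], cnp)
        assert d.status is RarityStatus.RARE

    def test_random_configurations_match_linear_scan(self, rng):
        refs = [
            _ref(
                f"v{i}",
                s := int(rng.integers(0, 5000)),
                s + int(rng.integers(10, 500)),
                freq=float(rng.uniform(0, 0.3)),
            )
            for i in range(50)
        ]
        cnp = ReferenceVariantSet("R", refs)
        for _ in range(200):
            s = int(rng.integers(0, 5000))
            call = _call("S", s, s + int(rng.integers(10, 500)))
            (d,) = filter_known_cnp([call], cnp, match_type=False)
            expected = any(
                v.frequency > 0.01
                and v.interval.start < call.interval.end
                and call.interval.start < v.interval.end
                for v in refs
            )
            assert (d.status is RarityStatus.KNOWN_CNP) == expected


class TestReferenceOverlapRule:
    def test_reciprocal_sixty_percent_excludes(self):
        ref = ReferenceVariantSet("DGV", [_ref("r1", 0, 1000)])
        (d,) = filter_reference_overlap([_call("S", 400, 1400)], [ref])
        assert d.status is RarityStatus.KNOWN_REFERENCE

    def test_one_sided_overlap_is_retained(self):
        # call covered 60% but reference only 30%: not reciprocal
        ref = ReferenceVariantSet("DGV", [_ref("r1", 0, 2000)])
        (d,) = filter_reference_overlap([_call("S", 1400, 2400)], [ref])
        assert d.status is RarityStatus.RARE

    def test_exactly_fifty_percent_counts_as_known(self):
        ref = ReferenceVariantSet("DGV", [_ref("r1", 0, 1000)])
        (d,) = filter_reference_overlap([_call("S", 500, 1500)], [ref])
        assert d.status is RarityStatus.KNOWN_REFERENCE

    def test_randomized_sets_match_all_pairs_oracle(self, rng):
        refs = [
            _ref(f"v{i}", s := int(rng.integers(0, 3000)), s + int(rng.integers(10, 400)))
            for i in range(40)
        ]
        refset = ReferenceVariantSet("R", refs)
        for _ in range(200):
            s = int(rng.integers(0, 3000))
            call = _call("S", s, s + int(rng.integers(10, 400)))
            (d,) = filter_reference_overlap([call], [refset], match_type=False)
            expected = any(linked_oracle(call.interval, v.interval, 0.5) for v in refs)
            assert (d.status is RarityStatus.KNOWN_REFERENCE) == expected


class TestSingletonRule:
    def test_identical_call_in_two_samples_is_non_singleton(self):
        calls = [_call("S1", 0, 1000), _call("S2", 0, 1000)]
        statuses = {d.call.sample_id: d.status for d in find_singletons(calls)}
        assert statuses == {"S1": RarityStatus.NON_SINGLETON, "S2": RarityStatus.NON_SINGLETON}

    def test_unique_call_is_rare(self):
        (d,) = find_singletons([_call("S1", 0, 1000)])
        assert d.status is RarityStatus.RARE

    def test_same_sample_repeats_stay_singleton(self):
        # two linked calls in ONE sample span a single-sample cluster
        calls = [_call("S1", 0, 1000), _call("S1", 100, 1100)]
        assert all(d.status is RarityStatus.RARE for d in find_singletons(calls))

    def test_planted_shared_loci_match_enumeration_oracle(self, rng):
        for _ in range(120):
            n = int(rng.integers(2, 9))
            calls = [
                _call(
                    f"S{int(rng.integers(0, 4))}",
                    s := int(rng.integers(0, 120)),
                    s + int(rng.integers(5, 60)),
                )
                for _ in range(n)
            ]
            decisions = find_singletons(calls)
            blocks = single_linkage_oracle([c.interval for c in calls], 0.5)
            expected_non = set()
            for block in blocks:
                if len({calls[i].sample_id for i in block}) >= 2:
                    expected_non.update(block)
            got_non = {
                i for i, d in enumerate(decisions) if d.status is RarityStatus.NON_SINGLETON
            }
            assert got_non == expected_non


class TestRarityChain:
    def test_statuses_are_exclusive_exhaustive_and_conserve(self, rng):
        cnp = ReferenceVariantSet("DGV", [_ref("c1", 0, 50_000, freq=0.1)])
        ref2 = ReferenceVariantSet("HapMap3", [_ref("h1", 100_000, 150_000)])
        calls = []
        for i in range(60):
            s = int(rng.integers(0, 400_000))
            calls.append(_call(f"S{int(rng.integers(0, 10))}", s, s + int(rng.integers(1000, 60_000))))
        decisions = assess_rarity(calls, cnp, [cnp, ref2])
        assert len(decisions) == len(calls)
        tally = dict(zip(*(rarity_tally(decisions).T.values)))
        assert tally["input"] == sum(v for k, v in tally.items() if k != "input")

    def test_rule_order_cnp_before_reference(self):
        # a call matching both rules is recorded under the CNP rule
        v = _ref("both", 0, 1000, freq=0.2)
        cnp = ReferenceVariantSet("DGV", [v])
        (d,) = assess_rarity([_call("S", 0, 1000)], cnp, [cnp])
        assert d.status is RarityStatus.KNOWN_CNP


class TestSpecificityAndRecurrence:
    GROUPS = {"C1": "case", "C2": "case", "C3": "case", "K1": "control", "K2": "control"}

    def test_case_call_without_control_twin_is_case_specific(self):
        case_sp, control_sp = case_control_specific(
            [_call("C1", 0, 1000), _call("K1", 500_000, 501_000)], self.GROUPS
        )
        assert [c.sample_id for c in case_sp] == ["C1"]
        assert [c.sample_id for c in control_sp] == ["K1"]

    def test_shared_locus_is_dropped_from_both_sides(self):
        calls = [_call("C1", 0, 1000), _call("K1", 100, 1100)]  # 90%/90% overlap
        case_sp, control_sp = case_control_specific(calls, self.GROUPS)
        assert case_sp == [] and control_sp == []

    def test_background_can_be_wider_than_candidates(self):
        candidate = _call("C1", 0, 1000)
        background = [candidate, _call("K1", 0, 1000)]
        case_sp, _ = case_control_specific([candidate], self.GROUPS, background=background)
        assert case_sp == []

    def test_specificity_matches_pairwise_oracle(self, rng):
        groups = {f"S{i}": ("case" if i < 3 else "control") for i in range(6)}
        for _ in range(120):
            n = int(rng.integers(2, 9))
            calls = [
                _call(
                    f"S{int(rng.integers(0, 6))}",
                    s := int(rng.integers(0, 120)),
                    s + int(rng.integers(5, 60)),
                )
                for _ in range(n)
            ]
            case_sp, control_sp = case_control_specific(calls, groups)
            got = {id(c) for c in case_sp} | {id(c) for c in control_sp}
            expected = set()
            for c in calls:
                rivals = [
                    r for r in calls
                    if groups[r.sample_id] != groups[c.sample_id]
                    and r.cnv_type is c.cnv_type
                ]
                if not any(linked_oracle(c.interval, r.interval, 0.5) for r in rivals):
                    expected.add(id(c))
            assert got == expected

    def test_recurrent_locus_in_three_cases(self):
        calls = [_call(s, 0, 50_000) for s in ("C1", "C2", "C3")]
        (cluster,) = find_recurrent(calls, self.GROUPS)
        assert cluster.n_cases == 3 and cluster.n_controls == 0
        assert cluster.locus == GenomicInterval("chr1", 0, 50_000)

    def test_all_singleton_input_yields_no_recurrence(self):
        calls = [_call("C1", 0, 1000), _call("C2", 500_000, 501_000)]
        assert find_recurrent(calls, self.GROUPS) == []

    def test_recurrence_matches_enumeration_oracle(self, rng):
        groups = {f"S{i}": "case" for i in range(5)}
        for _ in range(120):
            n = int(rng.integers(2, 9))
            calls = [
                _call(
                    f"S{int(rng.integers(0, 5))}",
                    s := int(rng.integers(0, 120)),
                    s + int(rng.integers(5, 60)),
                )
                for _ in range(n)
            ]
            got = {
                (r.locus.start, r.locus.end, r.sample_ids)
                for r in find_recurrent(calls, groups)
            }
            expected = set()
            for block in single_linkage_oracle([c.interval for c in calls], 0.5):
                samples = tuple(sorted({calls[i].sample_id for i in block}))
                if len(samples) >= 2:
                    expected.add(
                        (
                            min(calls[i].interval.start for i in block),
                            max(calls[i].interval.end for i in block),
                            samples,
                        )
                    )
            assert got == expected


class TestGenesAndBurden:
    def _annotation(self):
        return GenomeAnnotation(
            chromosome_lengths={"chr1": 10_000_000},
            genes=[
                GeneModel("g1", "ALPHA", GenomicInterval("chr1", 10_000, 20_000)),
                GeneModel("g2", "BETA", GenomicInterval("chr1", 100_000, 140_000)),
            ],
        )

    def test_contained_gene_listed_and_intergenic_dash(self):
        ann = self._annotation()
        calls = [_call("S", 5_000, 25_000), _call("S", 50_000, 60_000)]
        genes = annotate_genes(calls, ann)
        assert genes == [("ALPHA",), ()]
        assert genes_to_dash(genes[1]) == "-"

    def test_breakpoint_intersection_counts_as_disruption(self):
        ann = self._annotation()
        (genes,) = annotate_genes([_call("S", 139_999, 200_000)], ann)
        assert genes == ("BETA",)

    def test_random_calls_match_interval_scan(self, rng):
        genes = [
            GeneModel(f"g{i}", f"G{i}", GenomicInterval("chr1", s := int(rng.integers(0, 900_000)), s + int(rng.integers(100, 50_000))))
            for i in range(80)
        ]
        ann = GenomeAnnotation(chromosome_lengths={"chr1": 1_000_000}, genes=genes)
        for _ in range(200):
            s = int(rng.integers(0, 900_000))
            call = _call("S", s, s + int(rng.integers(100, 80_000)))
            (got,) = annotate_genes([call], ann)
            expected = sorted(
                g.symbol
                for g in genes
                if g.interval.start < call.interval.end and call.interval.start < g.interval.end
            )
            assert sorted(got) == expected

    def test_study_scale_per_genome_averages(self, rng):
        # 208 calls over 44 genomes and 283 over 72: the study-scale ratios
        case_calls = [
            _call(f"C{i % 44}", s := int(10_000 * i), s + 5_000) for i in range(208)
        ]
        control_calls = [
            _call(f"K{i % 72}", s := int(10_000 * i), s + 5_000, chrom="chr2")
            for i in range(283)
        ]
        report = burden_report(case_calls, control_calls, 44, 72)
        case_row = report.summary[report.summary.group == "case"].iloc[0]
        ctrl_row = report.summary[report.summary.group == "control"].iloc[0]
        assert f"{case_row.per_genome_mean:.2f}" == "4.73"
        assert case_row.per_genome_mean == pytest.approx(208 / 44)
        assert f"{ctrl_row.per_genome_mean:.2f}" == "3.93"
        assert case_row.n_gain + case_row.n_loss == case_row.n_cnvs

    def test_identical_length_samples_show_no_difference(self):
        case_calls = [_call("C1", i * 10_000, i * 10_000 + 5_000) for i in range(10)]
        control_calls = [
            _call("K1", i * 10_000, i * 10_000 + 5_000, chrom="chr2") for i in range(10)
        ]
        report = burden_report(case_calls, control_calls, 4, 4)
        assert report.length_statistic == 0.0 and report.length_p_value == 1.0

    def test_histogram_percentages_sum_to_hundred(self, rng):
        starts = [int(rng.integers(0, 10**7)) for _ in range(40)]
        case_calls = [
            _call("C1", s, s + int(rng.integers(1_000, 900_000))) for s in starts
        ]
        report = burden_report(case_calls, [], 4, 4)
        assert report.histogram.case_pct.sum() == pytest.approx(100.0)

    def test_empty_group_reports_zeros(self):
        report = burden_report([], [_call("K1", 0, 5_000)], 4, 4)
        row = report.summary[report.summary.group == "case"].iloc[0]
        assert row.n_cnvs == 0 and row.per_genome_mean == 0.0
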