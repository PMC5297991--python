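"""Variant filter funnel: VCF parsing, gates, merge, co-segregation."""

import itertools

import numpy as np
import pytest

from famcoseg.cascade import (
    HC,
    UG,
    FunnelIntegrityError,
    GenotypeCall,
    VariantRecord,
    cosegregation_filter,
    funnel_report,
    hard_filter,
    impact_filter,
    maf_filter,
    merge_callers,
    prioritize_cadd,
    read_annotated_vcf,
    region_filter,
    run_cascade,
)
from famcoseg.npl import LinkedRegion
from famcoseg.simulate import write_vcf


def rec(chrom="1", pos=100, ref="A", alt="G", qual=50.0, mq=60.0, fs=1.0,
        genotypes=None, **kw):
    genotypes = genotypes or {
        "a1": GenotypeCall(1, 20),
        "a2": GenotypeCall(1, 20),
        "ctl": GenotypeCall(0, 20),
    }
    return VariantRecord(chrom, pos, ref, alt, qual, mq, fs, genotypes, **kw)


TOY_VCF = """\
##fileformat=VCFv4.2
##INFO=<ID=EUR_MAF,Number=1,Type=Float,Description="x">
##INFO=<ID=EFF,Number=1,Type=String,Description="x">
##INFO=<ID=IMPACT,Number=1,Type=String,Description="x">
##INFO=<ID=CADD,Number=1,Type=Float,Description="x">
##INFO=<ID=MQ,Number=1,Type=Float,Description="x">
##INFO=<ID=FS,Number=1,Type=Float,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
1\t100\t.\tA\tG\t55\t.\tEUR_MAF=0.002;EFF=UTR_3_PRIME;IMPACT=MODIFIER;CADD=7.5;MQ=60;FS=2\tGT:DP\t0/1:18\t0/0:22
1\t200\t.\tC\tA,T\t90\t.\tMQ=55;FS=1\tGT:DP\t1/2:30\t0/1:12
1\t300\t.\tG\tC\t33\t.\tEFF=SYNONYMOUS_CODING;IMPACT=LOW;MQ=60;FS=0.5\tGT:DP\t./.:0\t1/1:9
"""


class TestVcfReading:
    def test_toy_vcf_parses_with_split_multiallelic(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(TOY_VCF)
        records = read_annotated_vcf(path, UG)
        # 3 sites, one with two alts -> 4 biallelic records
        assert len(records) == 4
        assert all(r.callers == {UG} for r in records)
        first = records[0]
        assert (first.pos, first.alt) == (100, "G")
        assert first.eur_maf == pytest.approx(0.002)
        assert first.cadd == pytest.approx(7.5)
        assert first.genotypes["s1"].dosage == 1
        assert first.genotypes["s1"].depth == 18
        # multi-allelic site: dosages are per split alt
        site2 = {r.alt: r for r in records if r.pos == 200}
        assert site2["A"].genotypes["s1"].dosage == 1
        assert site2["T"].genotypes["s1"].dosage == 1
        assert site2["T"].genotypes["s2"].dosage == 0
        # record without EUR_MAF: absent, treated as rare downstream
        assert site2["A"].eur_maf is None
        # missing genotype
        assert records[3].genotypes["s1"].dosage == -1

    def test_writer_reader_round_trip(self, tmp_path):
        records = [
            rec(pos=11, eur_maf=0.004, effect="INTRON", impact="MODIFIER",
                cadd=3.2, gene="G1"),
            rec(pos=22, genotypes={"a1": GenotypeCall(2, 9),
                                   "a2": GenotypeCall(-1, 0),
                                   "ctl": GenotypeCall(0, 15)}),
        ]
        path = tmp_path / "rt.vcf"
        write_vcf(records, path)
        back = read_annotated_vcf(path, UG)
        assert [(r.chrom, r.pos, r.ref, r.alt) for r in back] == \
            [(r.chrom, r.pos, r.ref, r.alt) for r in records]
        for orig, rb in zip(records, back):
            for s, g in orig.genotypes.items():
                assert rb.genotypes[s].dosage == g.dosage
                assert rb.genotypes[s].depth == g.depth
            # cyvcf2 surfaces Float INFO fields at float32 precision
            assert rb.eur_maf == pytest.approx(orig.eur_maf, rel=1e-6)
            assert rb.cadd == pytest.approx(orig.cadd, rel=1e-6)


class TestHardFilter:
    def test_boundary_pass(self):
        r = rec(qual=30.0, mq=40.0, fs=59.9,
                genotypes={"a1": GenotypeCall(1, 5)})
        assert hard_filter(r) == (True, None)

    def test_fs_at_sixty_fails_strand_bias(self):
        r = rec(fs=60.0)
        assert hard_filter(r) == (False, "strand_bias")

    def test_low_confidence_fails(self):
        assert hard_filter(rec(qual=29.9)) == (False, "confidence")

    def test_low_mq_fails(self):
        assert hard_filter(rec(mq=39.9)) == (False, "mapping_quality")

    def test_low_depth_rescued_when_called_in_both_affecteds(self):
        r = rec(genotypes={"a1": GenotypeCall(1, 2), "a2": GenotypeCall(1, 3),
                           "ctl": GenotypeCall(0, 30)})
        assert hard_filter(r)[0] is False
        assert hard_filter(r, rescue_samples=("a1", "a2"))[0] is True
        # not rescued if only one affected carries
        r2 = rec(genotypes={"a1": GenotypeCall(1, 2), "a2": GenotypeCall(0, 3)})
        assert hard_filter(r2, rescue_samples=("a1", "a2"))[0] is False


class TestSimpleGates:
    def test_maf(self):
        assert not maf_filter(rec(eur_maf=0.02))
        assert maf_filter(rec(eur_maf=None))
        assert maf_filter(rec(eur_maf=0.01))  # strict >

    def test_impact(self):
        assert not impact_filter(rec(effect="SYNONYMOUS_CODING", impact="LOW"))
        assert impact_filter(rec(effect="UTR_3_PRIME", impact="MODIFIER"))
        assert impact_filter(rec(effect="STOP_GAINED", impact="HIGH"))
        assert impact_filter(rec())  # missing impact kept

    def test_region_inclusive_bounds(self):
        regions = [LinkedRegion("1", 100, 200, 2.0, 1e-3, ())]
        assert region_filter([rec(pos=100)], regions)
        assert region_filter([rec(pos=200)], regions)
        assert not region_filter([rec(pos=201)], regions)
        assert not region_filter([rec(chrom="2", pos=150)], regions)

    def test_region_filter_matches_brute_force(self, rng):
        regions = [
            LinkedRegion("1", 3_000, 9_000, 2.0, 1e-3, ()),
            LinkedRegion("2", 1_000, 2_000, 1.7, 2e-3, ()),
        ]
        records = [
            rec(chrom=str(rng.integers(1, 4)), pos=int(rng.integers(1, 12_000)))
            for _ in range(50)
        ]
        expected = [
            r for r in records
            if any(
                r.chrom == g.chrom and g.start <= r.pos <= g.end
                for g in regions
            )
        ]
        assert region_filter(records, regions) == expected


class TestMerge:
    def test_disjoint_union(self):
        ug = [rec(pos=1), rec(pos=2)]
        hc = [rec(pos=3, callers=frozenset({HC})),
              rec(pos=4, callers=frozenset({HC})),
              rec(pos=5, callers=frozenset({HC}))]
        merged = merge_callers(ug, hc)
        assert len(merged) == 5
        assert all(len(r.callers) == 1 for r in merged)

    def test_identical_lists_dual_tagged(self):
        ug = [rec(pos=1), rec(pos=2)]
        hc = [rec(pos=1, callers=frozenset({HC})),
              rec(pos=2, callers=frozenset({HC}))]
        merged = merge_callers(ug, hc)
        assert len(merged) == 2
        assert all(r.callers == {UG, HC} for r in merged)
        assert not any(r.discordant_callers for r in merged)

    def test_discordant_genotypes_flagged(self):
        ug = [rec(pos=1)]
        hc = [rec(pos=1, callers=frozenset({HC}),
                  genotypes={"a1": GenotypeCall(2, 20),
                             "a2": GenotypeCall(1, 20),
                             "ctl": GenotypeCall(0, 20)})]
        merged = merge_callers(ug, hc)
        assert merged[0].discordant_callers
        assert merged[0].callers == {UG, HC}


class TestCosegregation:
    @pytest.mark.parametrize(
        "g1,g2,gc,kept",
        [
            (1, 1, 0, True),
            (1, 0, 0, False),
            (1, 1, 1, False),
            (2, 1, 0, True),
            (1, 1, -1, False),   # missing control: absence not assertable
            (-1, 1, 0, False),   # missing affected
        ],
    )
    def test_rule(self, g1, g2, gc, kept):
        r = rec(genotypes={"a1": GenotypeCall(g1, 20),
                           "a2": GenotypeCall(g2, 20),
                           "ctl": GenotypeCall(gc, 20)})
        got = cosegregation_filter([r], ("a1", "a2"), "ctl", "F1")
        assert bool(got) is kept


class TestPrioritize:
    def _cands(self, scores):
        out = []
        for i, s in enumerate(scores):
            r = rec(pos=10 + i, cadd=s, gene=f"G{i}")
            out.append(
                cosegregation_filter([r], ("a1", "a2"), "ctl", "F1")[0]
            )
        return out

    def test_strictly_above_threshold(self):
        ranked = prioritize_cadd(self._cands([5.0, 5.1, 20.0, None]))
        assert [c.record.cadd for c in ranked] == [20.0, 5.1]
        assert [c.priority_rank for c in ranked] == [1, 2]

    def test_include_list_appended_regardless_of_score(self):
        ranked = prioritize_cadd(
            self._cands([2.0, None, 9.0]), include_list=["G1"]
        )
        assert [c.record.gene for c in ranked] == ["G2", "G1"]
        assert ranked[-1].include_listed

    def test_empty_input(self):
        assert prioritize_cadd([]) == []


class TestFunnel:
    def test_valid_monotone_counts(self):
        report = funnel_report(
            [("a", {"UG": 10}), ("b", {"UG": 7}), ("c", {"UG": 7}),
             ("d", {"UG": 2})]
        )
        assert len(report.stages) == 4

    def test_increase_raises(self):
        with pytest.raises(FunnelIntegrityError):
            funnel_report([("a", {"UG": 10}), ("b", {"UG": 11})])


class TestOrderInvariance:
    def test_record_filters_commute(self, rng):
        """MAF/impact/quality/region gates give the same final set in any
        order on randomized toy inputs."""
        regions = [LinkedRegion("1", 1_000, 500_000, 2.0, 1e-3, ())]
        impacts = ["HIGH", "MODERATE", "LOW", "MODIFIER"]
        records = []
        for i in range(80):
            records.append(
                rec(
                    pos=int(rng.integers(1, 10**6)),
                    qual=float(rng.uniform(10, 100)),
                    mq=float(rng.uniform(30, 70)),
                    fs=float(rng.uniform(0, 80)),
                    eur_maf=None if rng.random() < 0.4 else float(rng.uniform(0, 0.05)),
                    impact=str(rng.choice(impacts)),
                )
            )
        gates = {
            "maf": lambda rs: [r for r in rs if maf_filter(r)],
            "impact": lambda rs: [r for r in rs if impact_filter(r)],
            "quality": lambda rs: [r for r in rs if hard_filter(r)[0]],
            "region": lambda rs: region_filter(rs, regions),
        }
        outcomes = set()
        for order in itertools.permutations(gates):
            rs = list(records)
            for name in order:
                rs = gates[name](rs)
            outcomes.add(tuple(r.key for r in rs))
        assert len(outcomes) == 1


class TestRunCascade:
    def test_end_to_end_keeps_causal_pattern(self):
        regions = [LinkedRegion("1", 1, 10**7, 2.0, 1e-3, ())]
        causal = rec(pos=500, cadd=15.0, gene="CAUSAL")
        noise = [
            rec(pos=600, eur_maf=0.05),                        # common
            rec(pos=700, impact="LOW", effect="SYNONYMOUS_CODING"),
            rec(pos=800, qual=10.0),                           # fails hard
            rec(pos=2 * 10**7),                                # outside region
            rec(pos=900, genotypes={"a1": GenotypeCall(1, 20),
                                    "a2": GenotypeCall(0, 20),
                                    "ctl": GenotypeCall(0, 20)}),
        ]
        candidates, report = run_cascade(
            [causal] + noise, [], regions, ("a1", "a2"), "ctl", "F1"
        )
        assert [c.record.gene for c in candidates] == ["CAUSAL"]
        counts = dict(report.stages)
        assert counts["raw"][UG] == 6
        assert counts["prioritized"]["union"] == 1
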