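"""Read filters, allele assignment, HWE exact test, informative-SNP
selection, and per-CpG allele counting."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asmmap.extraction import (
    allele_depths_from_reads,
    assign_allele,
    cpg_allele_counts,
    filter_reads,
    hwe_exact_test,
    informative_snps,
    resolve_pairs,
)
from asmmap.types import ALT, AMBIG, REF, AlleleRead, ConfigurationError, IndexSnp

from oracles import hwe_exact_oracle


def mkread(ch_unc=0, ch_tot=20, mate=1, strand="+", allele=REF, start=100,
           length=100, calls=((150, 1),), protocol="SureSelect", rid="r1"):
    return AlleleRead(
        read_id=rid, mate=mate, strand=strand, allele=allele, snp_id="snp1",
        cpg_calls=list(calls), ch_total=ch_tot, ch_unconverted=ch_unc,
        protocol=protocol, start=start, length=length,
    )


class TestFilterReads:
    def test_conversion_failure_boundary(self):
        # strictly more than 10% unconverted CH removes the read
        bad = mkread(ch_unc=3, ch_tot=20)  # 15%
        edge = mkread(ch_unc=2, ch_tot=20)  # exactly 10%
        kept = filter_reads([bad, edge], "SureSelect")
        assert [r.ch_unconverted for r in kept] == [2]

    @pytest.mark.parametrize(
        "protocol,mate,offset,masked",
        [
            ("Nextera", 2, 5, True),  # first 10 bp of mate-2 5'
            ("Nextera", 2, 11, False),
            ("Nextera", 1, 5, False),
            ("Nextera", 1, 98, True),  # last 2 bp of 3' (both mates)
            ("TruSeq", 1, 5, True),  # first 10 bp of both mates' 5'
            ("TruSeq", 2, 98, True),  # last 2 bp of mate-2 3'
            ("TruSeq", 1, 98, False),
            ("ACCEL", 2, 3, True),
            ("ACCEL", 1, 3, False),
            ("SureSelect", 2, 0, False),
        ],
    )
    def test_positional_masks(self, protocol, mate, offset, masked):
        read = mkread(mate=mate, calls=[(100 + offset, 1)], protocol=protocol)
        (out,) = filter_reads([read], protocol)
        assert (len(out.cpg_calls) == 0) == masked

    def test_minus_strand_offset_from_5prime(self):
        # on the minus strand the 5' end is the rightmost base
        read = mkread(mate=2, strand="-", calls=[(195, 1), (120, 0)][::-1])
        (out,) = filter_reads([read], "ACCEL")
        assert [p for p, _ in out.cpg_calls] == [120]

    def test_idempotent(self):
        reads = [mkread(ch_unc=3), mkread(), mkread(mate=2, calls=[(103, 1)])]
        once = filter_reads(reads, "Nextera")
        twice = filter_reads(once, "Nextera")
        assert once == twice

    def test_unknown_protocol(self):
        with pytest.raises(ConfigurationError):
            filter_reads([], "HiSeqMagic")


class TestAssignAllele:
    snp = IndexSnp("snp1", "chrS", 150, "A", "C")

    def test_discordant_pair_is_ambiguous(self):
        pair = [mkread(mate=1, allele=REF), mkread(mate=2, allele=ALT)]
        assert assign_allele(pair, self.snp) == AMBIG
        assert resolve_pairs(pair, self.snp) == []

    def test_ct_snp_confounded_strand_excluded(self):
        snp = IndexSnp("snp1", "chrS", 150, "C", "T")
        assert assign_allele([mkread(strand="+", allele=REF)], snp, "WGBS") is None
        assert assign_allele([mkread(strand="-", allele=REF)], snp, "WGBS") == REF

    def test_ga_snp_dropped_in_sureselect(self):
        snp = IndexSnp("snp1", "chrS", 150, "G", "A")
        assert assign_allele([mkread(strand="-", allele=ALT)], snp, "SureSelect") is None

    def test_ga_snp_strand_filtered_in_wgbs(self):
        snp = IndexSnp("snp1", "chrS", 150, "G", "A")
        assert assign_allele([mkread(strand="-", allele=ALT)], snp, "WGBS") is None
        assert assign_allele([mkread(strand="+", allele=ALT)], snp, "WGBS") == ALT

    def test_wrong_snp_rejected(self):
        other = IndexSnp("snp2", "chrS", 999, "A", "C")
        with pytest.raises(ValueError):
            assign_allele([mkread()], other)


class TestHweExact:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((2, 6, 2), 1.0),
            ((5, 0, 5), 252 / 184756),  # ~1.364e-3
            ((0, 10, 0), hwe_exact_oracle(0, 10, 0)),
            ((50, 20, 5), hwe_exact_oracle(50, 20, 5)),
        ],
    )
    def test_frozen_examples(self, counts, expected):
        assert hwe_exact_test(*counts) == pytest.approx(expected, rel=1e-9)

    def test_matches_oracle_exhaustively(self):
        for n_aa in range(0, 9):
            for n_ab in range(0, 9):
                for n_bb in range(0, 9):
                    if n_aa + n_ab + n_bb == 0:
                        continue
                    assert hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(
                        hwe_exact_oracle(n_aa, n_ab, n_bb), rel=1e-9
                    ), (n_aa, n_ab, n_bb)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    def test_valid_probability_and_label_symmetry(self, a, b, c):
        if a + b + c == 0:
            return
        p = hwe_exact_test(a, b, c)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(hwe_exact_test(c, b, a), rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestInformativeSnps:
    def _snps(self, genotypes=None):
        gts = genotypes or {f"s{i}": g for i, g in enumerate([0, 1, 1, 2, 1])}
        return [
            IndexSnp("snpA", "chrS", 1000, "A", "C", genotypes=gts),
            IndexSnp("snpB", "chrS", 5000, "A", "T", genotypes=gts),
        ]

    def test_depth_filters(self):
        snps = self._snps()
        depths = {"snpA": (4, 6), "snpB": (30, 40)}
        out = informative_snps(snps, depths, "s1")
        assert [s.snp_id for s in out] == ["snpB"]
        out = informative_snps(snps, {"snpA": (100, 150), "snpB": (10, 10)}, "s1")
        assert [s.snp_id for s in out] == ["snpB"]  # 250 > 200 total

    def test_blacklist_and_het_requirement(self):
        snps = self._snps()
        depths = {"snpA": (10, 10), "snpB": (10, 10)}
        out = informative_snps(snps, depths, "s0")  # homozygous sample
        assert out == []
        out = informative_snps(
            snps, depths, "s1", blacklist=[("chrS", 900, 1100)]
        )
        assert [s.snp_id for s in out] == ["snpB"]

    def test_hwe_cohort_filter(self):
        # grossly out-of-HWE SNP (all het) among well-behaved ones
        bad_gts = {f"s{i}": 1 for i in range(40)}
        ok_gts = {f"s{i}": g for i, g in enumerate([0, 1, 2, 1, 0, 1, 2, 1] * 5)}
        snps = [
            IndexSnp("bad", "chrS", 1000, "A", "C", genotypes=bad_gts),
            IndexSnp("ok", "chrS", 5000, "A", "T", genotypes=ok_gts),
        ]
        depths = {"bad": (10, 10), "ok": (10, 10)}
        out = informative_snps(snps, depths, "s1")
        assert [s.snp_id for s in out] == ["ok"]


class TestCpgAlleleCounts:
    snp = IndexSnp("snp1", "chrS", 1000, "A", "C")

    def _reads(self):
        reads = []
        for i in range(10):
            m = 1 if i < 9 else 0
            reads.append(mkread(rid=f"ref{i}", allele=REF, calls=[(900, m)]))
        for i in range(10):
            m = 1 if i < 1 else 0
            reads.append(mkread(rid=f"alt{i}", allele=ALT, calls=[(900, m)]))
        return reads

    def test_counting(self):
        (rec,) = cpg_allele_counts(self._reads(), self.snp)
        assert (rec.m_ref, rec.u_ref, rec.m_alt, rec.u_alt) == (9, 1, 1, 9)

    def test_single_allele_cpg_skipped(self):
        reads = [mkread(rid="r", allele=REF, calls=[(900, 1)])]
        assert cpg_allele_counts(reads, self.snp) == []

    def test_window_bounds_and_destroyed_flag(self):
        reads = self._reads() + [
            mkread(rid="farR", allele=REF, calls=[(2100, 1)]),
            mkread(rid="farA", allele=ALT, calls=[(2100, 1)]),
        ]
        recs = cpg_allele_counts(reads, self.snp, common_snp_positions={900})
        assert [r.cpg_pos for r in recs] == [900]  # 2100 outside 2 kb window
        assert recs[0].destroyed_by_common_snp

    def test_depths_count_read_pairs_once(self):
        reads = [
            mkread(rid="p", mate=1, allele=REF, calls=[(900, 1)]),
            mkread(rid="p", mate=2, allele=REF, calls=[(950, 1)]),
            mkread(rid="q", mate=1, allele=ALT, calls=[(900, 0)]),
        ]
        assert allele_depths_from_reads(reads) == {"snp1": (1, 1)}
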