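"""Cross-sample catalog: aggregation, ranking, switching, imprinting
flags, class assignment, and per-sample summary statistics."""
import numpy as np
import pytest

from asmmap.catalog import (
    aggregate_catalog,
    classify_asm_class,
    flag_imprinted,
    rank_loci,
    sample_summaries,
    switching_stats,
)
from asmmap.types import AsmDmr, CatalogEntry


def dmr(sample, snp, delta=0.3, cov=16.0, n_cov=6, n_asm=4):
    return AsmDmr(
        sample_id=sample, snp_id=snp, span=(100, 500), n_cpg_covered=n_cov,
        n_asm_cpg=n_asm, max_consecutive_asm=3, mean_delta=delta,
        wilcoxon_p=0.001, fdr_q=0.01, avg_allele_coverage=cov,
    )


class TestAggregate:
    def test_recurrence_rule(self):
        dmrs = {
            "s1": [dmr("s1", "snpA"), dmr("s1", "snpB")],
            "s2": [dmr("s2", "snpA", delta=-0.3)],
            "s3": [],
        }
        info = {"s1": {"snpA", "snpB"}, "s2": {"snpA", "snpB"}, "s3": {"snpA"}}
        recurrent, private = aggregate_catalog(dmrs, info)
        assert [e.snp_id for e in recurrent] == ["snpA"]
        assert recurrent[0].n_asm_samples == 2
        assert recurrent[0].n_informative_samples == 3
        assert recurrent[0].asm_sample_ids == {
            "s1": "REF_hyper", "s2": "ALT_hyper"
        }
        assert [e.snp_id for e in private] == ["snpB"]

    def test_uninformative_locus_absent(self):
        recurrent, private = aggregate_catalog({"s1": []}, {"s1": set()})
        assert recurrent == [] and private == []


class TestRanking:
    def test_confidence_score_geometric_mean(self):
        # components (coverage 16, 4 ASM samples, 50% of informative)
        dmrs = {f"s{i}": [dmr(f"s{i}", "snpA", cov=16.0)] for i in range(4)}
        info = {f"s{i}": {"snpA"} for i in range(8)}
        recurrent, _ = aggregate_catalog(dmrs, info)
        rank_loci(recurrent, dmrs)
        assert recurrent[0].confidence_score == pytest.approx(
            (16 * 4 * 50.0) ** (1 / 3)
        )
        assert recurrent[0].confidence_score == pytest.approx(14.73613, abs=1e-4)

    def test_tie_broken_lexicographically(self):
        dmrs = {
            "s1": [dmr("s1", "snpB"), dmr("s1", "snpA")],
            "s2": [dmr("s2", "snpB"), dmr("s2", "snpA")],
        }
        info = {"s1": {"snpA", "snpB"}, "s2": {"snpA", "snpB"}}
        recurrent, _ = aggregate_catalog(dmrs, info)
        rank_loci(recurrent, dmrs)
        by_id = {e.snp_id: e for e in recurrent}
        assert by_id["snpA"].overall_rank == 1
        assert by_id["snpB"].overall_rank == 2

    def test_strength_homogeneity(self):
        # doubling every strength component doubles the strength score
        base = {"s1": [dmr("s1", "A", delta=0.2, n_cov=8, n_asm=4)],
                "s2": [dmr("s2", "A", delta=0.2, n_cov=8, n_asm=4)]}
        dbl = {"s1": [dmr("s1", "A", delta=0.4, n_cov=8, n_asm=8)],
               "s2": [dmr("s2", "A", delta=0.4, n_cov=8, n_asm=8)]}
        info = {"s1": {"A"}, "s2": {"A"}}
        e1, _ = aggregate_catalog(base, info)
        e2, _ = aggregate_catalog(dbl, info)
        rank_loci(e1, base)
        rank_loci(e2, dbl)
        # components: (delta, n_asm, pct) -> x2 each = x2 geometric mean
        assert e2[0].strength_score == pytest.approx(2 * e1[0].strength_score)

    def test_ranks_are_permutation(self, pipeline_result):
        ranks = sorted(e.overall_rank for e in pipeline_result.catalog)
        assert ranks == list(range(1, len(ranks) + 1))


class TestSwitching:
    def _entry(self, directions):
        label = {"R": "REF_hyper", "A": "ALT_hyper"}
        return CatalogEntry(
            snp_id="snpA", n_informative_samples=len(directions),
            n_asm_samples=len(directions),
            asm_sample_ids={
                f"s{i}": label[d] for i, d in enumerate(directions)
            },
        )

    def test_no_switch(self):
        (e,) = switching_stats([self._entry("RRRR")], {"snpA": 4})
        assert e.switching_fraction == 0.0 and e.switch_flag is False

    def test_minority_fraction(self):
        (e,) = switching_stats([self._entry(("R", "R", "R", "A", "A"))], {"snpA": 5})
        assert e.switching_fraction == pytest.approx(0.4)
        assert e.switch_flag is True

    def test_not_scored_at_two_het_samples(self):
        (e,) = switching_stats([self._entry("RA")], {"snpA": 2})
        assert e.switching_fraction is None and e.switch_flag is None


class TestImprintFlags:
    def _entry(self, n_individuals, n_switch):
        dirs = ["REF_hyper"] * (n_individuals - n_switch) + ["ALT_hyper"] * n_switch
        e = CatalogEntry(
            snp_id="snpA", n_informative_samples=n_individuals,
            n_asm_samples=n_individuals,
            asm_sample_ids={f"s{i}": d for i, d in enumerate(dirs)},
        )
        switching_stats([e], {"snpA": n_individuals})
        return e

    def test_within_150kb_window_is_known(self):
        e = self._entry(4, 0)
        flag_imprinted(
            [e], {"snpA": ("chrS", 100_000)}, [("chrS", 174_000, "IMP1")],
            {f"s{i}": f"ind{i}" for i in range(4)},
        )
        assert e.imprint_flag == "known"  # 74 kb from the TSS

    def test_outside_window_not_known(self):
        e = self._entry(4, 0)
        flag_imprinted(
            [e], {"snpA": ("chrS", 100_000)}, [("chrS", 176_000, "IMP1")],
            {f"s{i}": f"ind{i}" for i in range(4)},
        )
        assert e.imprint_flag == "none"

    @pytest.mark.parametrize("n_switch,expected", [(3, "candidate"), (1, "none")])
    def test_candidate_rule(self, n_switch, expected):
        e = self._entry(12, n_switch)  # 25% vs 8% switching
        flag_imprinted(
            [e], {"snpA": ("chrS", 100_000)}, [],
            {f"s{i}": f"ind{i}" for i in range(12)},
        )
        assert e.imprint_flag == expected

    def test_ten_individuals_is_not_enough(self):
        e = self._entry(10, 3)
        flag_imprinted(
            [e], {"snpA": ("chrS", 100_000)}, [],
            {f"s{i}": f"ind{i}" for i in range(10)},
        )
        assert e.imprint_flag == "none"


class TestAsmClass:
    cancer_map = {"myeloma": True, "GBM": True, "LCL": True, "Tcell": False}

    def _entry(self, samples):
        return CatalogEntry(
            snp_id="snpA", n_informative_samples=4, n_asm_samples=len(samples),
            asm_sample_ids={s: "REF_hyper" for s in samples},
        )

    def test_cancer_only(self):
        (e,) = classify_asm_class([self._entry(["myeloma", "GBM"])], self.cancer_map)
        assert e.asm_class == "cancer_only_ASM"

    def test_mixed_is_normal(self):
        (e,) = classify_asm_class([self._entry(["Tcell", "myeloma"])], self.cancer_map)
        assert e.asm_class == "normal_ASM"

    def test_lcl_counts_as_cancer(self):
        (e,) = classify_asm_class([self._entry(["LCL"])], self.cancer_map)
        assert e.asm_class == "cancer_only_ASM"

    def test_unlabelled_sample_rejected(self):
        with pytest.raises(ValueError):
            classify_asm_class([self._entry(["mystery"])], self.cancer_map)

    def test_partitions_catalog(self, pipeline_result):
        assert all(
            e.asm_class in ("normal_ASM", "cancer_only_ASM")
            for e in pipeline_result.catalog
        )


class TestSampleSummaries:
    def test_exact_fold(self):
        per_sample = {}
        for i in range(4):
            per_sample[f"n{i}"] = dict(cancer=False, global_meth=0.8 - 0.01 * i,
                                       n_asm=2, n_informative=100)
        for i in range(4):
            per_sample[f"c{i}"] = dict(cancer=True, global_meth=0.6 - 0.01 * i,
                                       n_asm=10, n_informative=100)
        _, stats = sample_summaries(per_sample)
        assert stats["fold"] == pytest.approx(5.0)
        assert stats["rho"] < 0

    def test_degenerate_inputs_yield_null(self):
        per_sample = {
            f"s{i}": dict(cancer=False, global_meth=0.5, n_asm=1, n_informative=10)
            for i in range(5)
        }
        _, stats = sample_summaries(per_sample)
        assert stats["rho"] is None and stats["fold"] is None
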