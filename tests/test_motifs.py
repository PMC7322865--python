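"""PWM scoring, exact nulls, disruption calls, motif enrichment, and
affinity-methylation regressions."""
import numpy as np
import pytest

from asmmap.motifs import (
    call_disruptive,
    cpg_adjusted_correlation,
    motif_asm_correlation,
    motif_enrichment,
    sample_background,
    score_allele_pwm,
    score_snps,
)
from asmmap.pwm import Pwm, SnpWindow, read_jaspar, revcomp, write_jaspar
from asmmap.types import FormatError, MotifOccurrence

from oracles import pwm_best_score_dist


@pytest.fixture(scope="module")
def small_pwm():
    # well-separated column ratios so grid rounding cannot cross score gaps
    counts = np.array([[8, 4, 2, 1], [1, 8, 4, 2], [2, 1, 8, 4]], dtype=float)
    return Pwm.from_counts("tiny", counts, pseudocount=0.25)


class TestPwmContainer:
    def test_columns_must_sum_to_one(self):
        with pytest.raises(FormatError):
            Pwm("bad", np.array([[0.5, 0.2, 0.2, 0.2], [0.25] * 4]))

    def test_needs_two_columns(self):
        with pytest.raises(FormatError):
            Pwm("short", np.array([[0.25, 0.25, 0.25, 0.25]]))

    def test_jaspar_round_trip(self, tmp_path, small_pwm):
        path = tmp_path / "m.jaspar"
        write_jaspar([small_pwm], path)
        (back,) = read_jaspar(path)
        assert back.motif_id == small_pwm.motif_id
        assert np.allclose(back.matrix, small_pwm.matrix, atol=1e-4)

    def test_jaspar_three_rows_rejected(self, tmp_path):
        path = tmp_path / "bad.jaspar"
        path.write_text(">M1 M1\nA [ 1 2 ]\nC [ 1 2 ]\nG [ 1 2 ]\n")
        with pytest.raises(FormatError):
            read_jaspar(path)


class TestScoring:
    def test_identical_windows_null(self, small_pwm):
        w = SnpWindow("s", "ACGTAC", "ACGTAC", 2)
        occ = score_allele_pwm(w, small_pwm)
        assert occ.score_diff == 0
        assert occ.p_diff == 1.0

    def test_window_shorter_than_motif_rejected(self, small_pwm):
        with pytest.raises(FormatError):
            score_allele_pwm(SnpWindow("s", "AC", "AG", 1), small_pwm)

    def test_reverse_complement_symmetry(self, small_pwm):
        # consensus ACG embedded forward: the best hit is strand-unique
        w = SnpWindow("s", "AACGAAA", "AATGAAA", 2)
        occ = score_allele_pwm(w, small_pwm)
        n = len(w.seq_ref)
        w_rc = SnpWindow("s", revcomp(w.seq_ref), revcomp(w.seq_alt), n - 3)
        occ_rc = score_allele_pwm(w_rc, small_pwm)
        assert occ.score_ref == pytest.approx(occ_rc.score_ref)
        assert occ.score_alt == pytest.approx(occ_rc.score_alt)
        assert (occ.strand, occ_rc.strand) == ("+", "-")

    def test_allele_swap_negates_diff(self, small_pwm):
        w = SnpWindow("s", "ACGTACG", "ACTTACG", 2)
        fwd = score_allele_pwm(w, small_pwm)
        rev = score_allele_pwm(SnpWindow("s", w.seq_alt, w.seq_ref, 2), small_pwm)
        assert fwd.score_diff == pytest.approx(-rev.score_diff)
        assert fwd.p_diff == pytest.approx(rev.p_diff)

    def test_single_offset_null_matches_enumeration(self, small_pwm):
        """Exact-null check: the per-offset score distribution equals
        exhaustive enumeration over all 4^L windows."""
        from itertools import product

        from asmmap.pwm import BASE_INDEX

        lr = small_pwm.logratio
        scores = sorted(
            sum(lr[i, b] for i, b in enumerate(win))
            for win in product(range(4), repeat=3)
        )
        n = len(scores)
        for v in np.unique(np.round(scores, 9)):
            exact = sum(s >= v - 1e-9 for s in scores) / n
            assert small_pwm.sf_single(float(v)) == pytest.approx(exact, abs=1e-12)

    def test_best_hit_p_bounds_enumeration(self, small_pwm):
        """The Sidak-combined best-hit p brackets the exhaustive best-score
        tail over all windows of length 5 (motif length 3)."""
        best = pwm_best_score_dist(small_pwm.logratio, 5)
        n = len(best)
        # alignments covering a central SNP in a length-5 window: 3 x 2 strands
        for v in (best[-1], best[n // 2], best[n // 4]):
            exact = sum(s >= v - 1e-9 for s in best) / n
            ours = small_pwm.best_hit_p(float(v), 6)
            assert ours >= exact * 0.3  # Sidak over-counts dependence at most mildly
            assert ours <= min(6 * small_pwm.sf_single(float(v) - 0.01), 1.0) + 1e-9


class TestPlantedLandscape:
    def test_planted_dpwm_recovered_by_scorer(self, sim_bundle):
        """Independent check: with consensus embedding, the scorer's
        best-hit score difference equals the planted critical-column log2
        probability ratio exactly."""
        from asmmap.simulate import simulate_motif_landscape

        truth = sim_bundle["truth"]
        pwms = {p.motif_id: p for p in sim_bundle["pwms"]}
        clean = simulate_motif_landscape(
            sim_bundle["cohort"], truth, sim_bundle["pwms"],
            degenerate_positions=False,
        )
        checked = 0
        for lid, motif_id in truth.motif_id.items():
            if motif_id is None:
                continue
            occ = score_allele_pwm(clean[lid], pwms[motif_id])
            assert occ.score_diff == pytest.approx(
                truth.planted_dpwm[lid], abs=1e-6
            )
            checked += 1
        assert checked > 0

    def test_degenerate_occurrences_recover_dpwm_approximately(self, sim_bundle):
        truth = sim_bundle["truth"]
        pwms = {p.motif_id: p for p in sim_bundle["pwms"]}
        diffs = []
        for lid, motif_id in truth.motif_id.items():
            if motif_id is None:
                continue
            occ = score_allele_pwm(sim_bundle["windows"][lid], pwms[motif_id])
            assert occ.score_diff <= truth.planted_dpwm[lid] + 1e-6
            diffs.append(occ.score_diff - truth.planted_dpwm[lid])
        assert np.median(np.abs(diffs)) < 0.5

    def test_null_loci_have_zero_planted_diff(self, sim_bundle):
        truth = sim_bundle["truth"]
        for lid, cls in truth.locus_class.items():
            if cls != "genotype_ASM":
                assert truth.planted_dpwm[lid] == 0.0
        # the REF/ALT windows differ only at the SNP base
        for w in sim_bundle["windows"].values():
            i = w.snp_index
            assert w.seq_ref[:i] == w.seq_alt[:i]
            assert w.seq_ref[i + 1 :] == w.seq_alt[i + 1 :]
            assert w.seq_ref[i] != w.seq_alt[i]

    def test_disruption_recovery_on_asm_family(self, sim_bundle):
        truth = sim_bundle["truth"]
        asm_ids = {
            lid for lid, c in truth.locus_class.items() if c != "none"
        }
        occ = score_snps(
            {k: w for k, w in sim_bundle["windows"].items() if k in asm_ids},
            sim_bundle["pwms"],
        )
        dis = call_disruptive(occ)
        planted = {
            lid for lid, c in truth.locus_class.items() if c == "genotype_ASM"
        }
        hits = {o.snp_id for o in dis if o.motif_id == truth.motif_id.get(o.snp_id)}
        false = [o for o in dis if o.snp_id not in planted]
        assert len(hits & planted) >= 0.7 * len(planted)
        assert len(false) <= max(1, 0.1 * len(dis))


def occ(motif="M1", snp="s1", diff=1.0, q=0.01, p_ref=0.001, p_alt=0.5,
        delta=np.nan, cpg=False):
    return MotifOccurrence(
        snp_id=snp, motif_id=motif, strand="+", snp_offset=0,
        score_ref=diff, score_alt=0.0, p_ref=p_ref, p_alt=p_alt,
        q_diff=q, contains_cpg=cpg, mean_delta_meth=delta,
    )


class TestDisruptionGate:
    def test_thresholds(self):
        keep = occ(q=0.01, p_ref=0.001)
        weak_binding = occ(q=0.01, p_ref=0.02, p_alt=0.02)
        weak_diff = occ(q=0.20, p_ref=0.001)
        assert call_disruptive([keep, weak_binding, weak_diff]) == [keep]


class TestEnrichment:
    def test_or_matches_2x2_arithmetic(self):
        asm = {f"a{i}" for i in range(100)}
        bg = {f"b{i}" for i in range(100)}
        hit = {f"a{i}" for i in range(30)} | {f"b{i}" for i in range(10)}
        df = motif_enrichment({"M1": hit}, asm, bg)
        expected = (30 * 90) / (70 * 10)
        assert df.loc[0, "odds_ratio"] == pytest.approx(expected, rel=1e-4)

    def test_equal_proportions_null(self):
        asm = {f"a{i}" for i in range(50)}
        bg = {f"b{i}" for i in range(50)}
        hit = {f"a{i}" for i in range(10)} | {f"b{i}" for i in range(10)}
        df = motif_enrichment({"M1": hit}, asm, bg)
        assert df.loc[0, "odds_ratio"] == pytest.approx(1.0, abs=1e-6)
        assert not df.loc[0, "enriched"]

    def test_minimum_occurrence_filter(self):
        asm = {f"a{i}" for i in range(50)}
        bg = {f"b{i}" for i in range(50)}
        df = motif_enrichment({"M1": {"a0", "a1"}}, asm, bg, min_occurrences=10)
        assert df.empty

    def test_background_sampler_seeded_and_capped(self):
        pool = [f"x{i}" for i in range(500)]
        a = sample_background(pool, 50, ratio=3, cap=120, seed=9)
        b = sample_background(pool, 50, ratio=3, cap=120, seed=9)
        assert a == b and len(a) == 120


class TestCorrelation:
    def test_exact_line(self):
        occs = [
            occ(snp=f"s{i}", diff=x, delta=-0.1 * x)
            for i, x in enumerate(np.linspace(1, 5, 15))
        ]
        df = motif_asm_correlation(occs)
        assert df.loc[0, "slope"] == pytest.approx(-0.1)
        assert df.loc[0, "r2"] == pytest.approx(1.0)
        assert bool(df.loc[0, "significant"])

    def test_noisy_slope_within_2se(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 6, size=50)
        y = -0.08 * x + rng.normal(0, 0.05, size=50)
        occs = [
            occ(snp=f"s{i}", diff=xi, delta=yi) for i, (xi, yi) in enumerate(zip(x, y))
        ]
        df = motif_asm_correlation(occs)
        assert abs(df.loc[0, "slope"] - (-0.08)) < 2 * df.loc[0, "slope_se"]

    def test_ten_occurrences_skipped(self):
        occs = [occ(snp=f"s{i}", diff=i, delta=-0.1 * i) for i in range(10)]
        assert motif_asm_correlation(occs).empty


class TestCpgAdjustment:
    def test_independent_flag_leaves_slope(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1, 6, 40)
        y = -0.1 * x + rng.normal(0, 0.02, 40)
        occs = [
            occ(snp=f"s{i}", diff=xi, delta=yi, cpg=bool(i % 2))
            for i, (xi, yi) in enumerate(zip(x, y))
        ]
        adj = cpg_adjusted_correlation(occs)
        raw = motif_asm_correlation(occs).loc[0, "slope"]
        assert adj["slope"] == pytest.approx(raw, abs=0.01)

    def test_constant_shift_does_not_move_affinity_coefficient(self):
        x = np.linspace(1, 6, 30)
        occs = [
            occ(snp=f"s{i}", diff=xi, delta=-0.1 * xi + 0.05 * (i % 2),
                cpg=bool(i % 2))
            for i, xi in enumerate(x)
        ]
        adj = cpg_adjusted_correlation(occs)
        assert adj["slope"] == pytest.approx(-0.1, abs=1e-6)
        assert adj["cpg_coef"] == pytest.approx(0.05, abs=1e-6)

    def test_single_stratum_skipped(self):
        occs = [occ(snp=f"s{i}", diff=i, delta=-0.1 * i, cpg=True) for i in range(20)]
        assert cpg_adjusted_correlation(occs) is None


class TestChipContext:
    def test_flags_and_retention_rules(self):
        from asmmap.motifs import annotate_chip_context

        occs = [occ(motif="M1", snp=f"s{i}") for i in range(12)]
        occs += [occ(motif="M2", snp=f"s{i}") for i in range(9)]
        positions = {f"s{i}": ("chrS", 1000 + i) for i in range(12)}
        peaks = {
            "M1": [("chrS", 900, 1100)],
            "M2": [("chrS", 900, 1100)],
        }
        rates = {"M1": (0.10, 0.009), "M2": (0.10, 0.009)}
        flags, retained = annotate_chip_context(occs, peaks, positions, rates)
        assert flags[("s0", "M1")] is True
        # M2 has only 9 in-peak occurrences -> class dropped
        assert retained == {"M1"}
        # a motif failing the 10-fold enrichment rule is dropped too
        rates["M1"] = (0.10, 0.05)
        _, retained = annotate_chip_context(occs, peaks, positions, rates)
        assert retained == set()
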