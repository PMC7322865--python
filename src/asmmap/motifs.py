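"""Allelic binding-affinity scoring at index SNPs and motif-level ASM
mechanism tests: disruption calls, enrichment among ASM loci, and
regression of allelic methylation differences on allelic affinity
differences (with CpG-presence adjustment).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .pwm import BASE_INDEX, COMPLEMENT, Pwm, SnpWindow, revcomp
from .types import FormatError, MotifOccurrence


def _alignments(window: SnpWindow, L: int):
    """All (offset, strand) alignments of an L-mer covering the SNP."""
    i, n = window.snp_index, len(window.seq_ref)
    lo = max(0, i - L + 1)
    hi = min(n - L, i)
    return [(t, s) for t in range(lo, hi + 1) for s in ("+", "-")]


def _score_alignment(seq: str, t: int, strand: str, pwm: Pwm) -> float:
    sub = seq[t : t + len(pwm)]
    if strand == "-":
        sub = revcomp(sub)
    return pwm.score_window(sub)


def score_allele_pwm(window: SnpWindow, pwm: Pwm) -> MotifOccurrence:
    """Best-hit log2 likelihood-ratio scores of both alleles with exact
    best-score p-values and a score-difference p-value.

    The best hit is searched over all offsets and strands whose L-mer
    contains the SNP; per-allele significance uses the exact single-offset
    null combined over alignments (Sidak); the score-difference null
    conditions on the SNP base of the stronger allele's best alignment.
    """
    L = len(pwm)
    if len(window.seq_ref) < L:
        raise FormatError(
            f"{window.snp_id}: window shorter than motif {pwm.motif_id}"
        )
    aligns = _alignments(window, L)
    best = {}
    for seq, allele in ((window.seq_ref, "ref"), (window.seq_alt, "alt")):
        scores = [(_score_alignment(seq, t, s, pwm), t, s) for t, s in aligns]
        best[allele] = max(scores, key=lambda x: x[0])
    score_ref, t_ref, s_ref = best["ref"]
    score_alt, t_alt, s_alt = best["alt"]
    n_align = len(aligns)
    p_ref = pwm.best_hit_p(score_ref, n_align)
    p_alt = pwm.best_hit_p(score_alt, n_align)
    # report the stronger allele's alignment as the occurrence
    t, s = (t_ref, s_ref) if score_ref >= score_alt else (t_alt, s_alt)
    i = window.snp_index
    j = i - t if s == "+" else L - 1 - (i - t)
    obs_diff = score_ref - score_alt
    p_diff = 1.0 if obs_diff == 0 else pwm.diff_p(obs_diff)
    hit_ref = window.seq_ref[t : t + L]
    hit_alt = window.seq_alt[t : t + L]
    contains_cpg = "CG" in hit_ref or "CG" in hit_alt
    return MotifOccurrence(
        snp_id=window.snp_id, motif_id=pwm.motif_id, strand=s, snp_offset=j,
        score_ref=score_ref, score_alt=score_alt, p_ref=p_ref, p_alt=p_alt,
        p_diff=p_diff, contains_cpg=contains_cpg,
    )


def score_snps(windows, pwms):
    """Score every motif x SNP combination and assign B-H corrected
    ``q_diff`` across the whole family of tests."""
    occurrences = [
        score_allele_pwm(w, pwm)
        for w in (windows.values() if isinstance(windows, dict) else windows)
        for pwm in pwms
    ]
    if occurrences:
        _, qvals, _, _ = multipletests(
            [o.p_diff for o in occurrences], method="fdr_bh"
        )
        for o, q in zip(occurrences, qvals):
            o.q_diff = float(q)
    return occurrences


def call_disruptive(occurrences, q_max: float = 0.05, p_binding: float = 0.005):
    """Occurrences with a significant allelic score difference and a
    significant binding likelihood on at least one allele."""
    return [
        o for o in occurrences
        if o.q_diff < q_max and min(o.p_ref, o.p_alt) < p_binding
    ]


def sample_background(non_asm_snps, n_asm: int, ratio: int = 3,
                      cap: int = 40_000, seed: int = 0):
    """Seeded random sample of informative non-ASM SNPs, sized at
    ``ratio`` x the ASM count or ``cap``, whichever is smaller."""
    non_asm_snps = sorted(non_asm_snps)
    size = min(ratio * n_asm, cap, len(non_asm_snps))
    rng = np.random.default_rng(seed)
    return set(rng.choice(non_asm_snps, size=size, replace=False))


def _logit_or(y, x):
    """Odds ratio + Wald p from a bivariate logistic regression, falling
    back to a Haldane-corrected 2x2 with Fisher p under separation."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    a = int(((y == 1) & (x == 1)).sum())
    b = int(((y == 1) & (x == 0)).sum())
    c = int(((y == 0) & (x == 1)).sum())
    d = int(((y == 0) & (x == 0)).sum())
    if min(a, b, c, d) == 0:
        _, p = stats.fisher_exact([[a, b], [c, d]])
        num_zero, den_zero = (a == 0 or d == 0), (b == 0 or c == 0)
        if den_zero and not num_zero:
            return float("inf"), float(p)
        if num_zero and not den_zero:
            return 0.0, float(p)
        or_h = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        return or_h, float(p)
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        return float(np.exp(fit.params[1])), float(fit.pvalues[1])
    except (PerfectSeparationError, np.linalg.LinAlgError):
        _, p = stats.fisher_exact([[a, b], [c, d]])
        return (a * d) / (b * c), float(p)


def motif_enrichment(disrupted_by_motif: dict, asm_snps, background_snps,
                     or_min: float = 2.0, q_max: float = 0.05,
                     min_occurrences: int = 10) -> pd.DataFrame:
    """Per-motif enrichment of disruptive occurrences among ASM SNPs.

    Logistic regression of ASM status on the disruption indicator over
    ASM + sampled background SNPs; B-H across motifs; ``enriched`` flags
    OR > ``or_min`` and q < ``q_max``.  Motifs with fewer than
    ``min_occurrences`` disrupted SNPs overall are excluded.
    """
    asm_snps = set(asm_snps)
    background_snps = set(background_snps)
    universe = sorted(asm_snps) + sorted(background_snps)
    y = np.array([1] * len(asm_snps) + [0] * len(background_snps))
    rows = []
    for motif_id in sorted(disrupted_by_motif):
        hit = disrupted_by_motif[motif_id]
        x = np.array([s in hit for s in universe], dtype=float)
        if x.sum() < min_occurrences:
            continue
        odds, p = _logit_or(y, x)
        rows.append(dict(motif_id=motif_id, odds_ratio=odds, p=p,
                         n_disrupted=int(x.sum())))
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    _, q, _, _ = multipletests(df["p"], method="fdr_bh")
    df["q"] = q
    df["enriched"] = (df["odds_ratio"] > or_min) & (df["q"] < q_max)
    return df


def motif_asm_correlation(occurrences, min_occurrences: int = 10,
                          fdr: float = 0.05, r2_min: float = 0.4) -> pd.DataFrame:
    """Per-motif OLS of mean allelic methylation difference on allelic
    affinity difference.  Motifs with <= ``min_occurrences`` disrupted
    occurrences are skipped; significance requires B-H q < ``fdr`` and
    R^2 > ``r2_min``.  A negative slope is the inverse (affinity up,
    methylation down) correlation.
    """
    by_motif: dict = {}
    for o in occurrences:
        by_motif.setdefault(o.motif_id, []).append(o)
    rows = []
    for motif_id in sorted(by_motif):
        occ = [o for o in by_motif[motif_id] if np.isfinite(o.mean_delta_meth)]
        if len(occ) <= min_occurrences:
            continue
        x = np.array([o.score_diff for o in occ])
        yv = np.array([o.mean_delta_meth for o in occ])
        fit = sm.OLS(yv, sm.add_constant(x)).fit()
        rows.append(
            dict(motif_id=motif_id, slope=float(fit.params[1]),
                 slope_se=float(fit.bse[1]), r2=float(fit.rsquared),
                 p=float(fit.pvalues[1]), n=len(occ))
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    _, q, _, _ = multipletests(df["p"], method="fdr_bh")
    df["q"] = q
    df["significant"] = (df["q"] < fdr) & (df["r2"] > r2_min)
    return df


def cpg_adjusted_correlation(occurrences, min_per_stratum: int = 3):
    """Multivariate OLS of methylation difference on affinity difference
    adjusting for CpG presence in the motif occurrence.  Requires at
    least ``min_per_stratum`` CpG-containing and non-CpG occurrences;
    returns ``None`` when a stratum is too small."""
    occ = [o for o in occurrences if np.isfinite(o.mean_delta_meth)]
    n_cpg = sum(o.contains_cpg for o in occ)
    if n_cpg < min_per_stratum or len(occ) - n_cpg < min_per_stratum:
        return None
    x = np.column_stack(
        [[o.score_diff for o in occ], [float(o.contains_cpg) for o in occ]]
    )
    yv = np.array([o.mean_delta_meth for o in occ])
    fit = sm.OLS(yv, sm.add_constant(x)).fit()
    return dict(
        slope=float(fit.params[1]), slope_p=float(fit.pvalues[1]),
        cpg_coef=float(fit.params[2]), cpg_p=float(fit.pvalues[2]),
        r2=float(fit.rsquared), n=len(occ),
    )


def annotate_chip_context(occurrences, chip_peaks: dict, snp_positions: dict,
                          asm_rate_by_motif: dict | None = None,
                          min_occurrences: int = 10, min_fold: float = 10.0):
    """Flag occurrences inside a cognate TF ChIP peak.

    ``chip_peaks`` maps motif_id -> [(chrom, start, end)] of cognate
    peaks; ``snp_positions`` maps snp_id -> (chrom, pos).  Returns
    ``(flags, retained_motifs)`` where a motif class is retained only
    with >= ``min_occurrences`` in-peak occurrences and (when
    ``asm_rate_by_motif`` supplies (asm_rate, background_rate)) a
    >= ``min_fold`` ASM enrichment.
    """
    trees: dict = {}
    for motif_id, peaks in chip_peaks.items():
        tree = IntervalTree()
        for chrom, start, end in peaks:
            if end > start:
                tree[start:end] = chrom
        trees[motif_id] = tree
    flags = {}
    counts: dict = {}
    for o in occurrences:
        chrom, pos = snp_positions[o.snp_id]
        tree = trees.get(o.motif_id)
        inside = bool(tree is not None and tree.overlaps(pos, pos + 1))
        flags[(o.snp_id, o.motif_id)] = inside
        if inside:
            counts[o.motif_id] = counts.get(o.motif_id, 0) + 1
    retained = set()
    for motif_id, n in counts.items():
        if n < min_occurrences:
            continue
        if asm_rate_by_motif is not None:
            asm_rate, bg_rate = asm_rate_by_motif.get(motif_id, (0.0, 1.0))
            if bg_rate <= 0 or asm_rate / bg_rate < min_fold:
                continue
        retained.add(motif_id)
    return flags, retained
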