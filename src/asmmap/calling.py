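"""CpG- and DMR-level ASM calling, DMR merging, and the deep-coverage
bootstrap test for targeted validation data.

A DMR is called in one sample at one index SNP when (i) at least 3 CpGs
show significant allelic asymmetry (two-sided Fisher p < 0.05), of which
at least 2 are consecutive in the ordered list of covered eligible CpGs;
(ii) the absolute mean methylation difference over all covered CpGs
between the first and last asymmetric CpG exceeds 20%; and (iii) a
Wilcoxon test across per-CpG allele-fraction pairs in that span survives
Benjamini-Hochberg correction (q < 0.05) over all candidate windows of
the sample.
"""
from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import AsmDmr, CpGAlleleCounts, CpgAsmResult


def fisher_cpg(counts: CpGAlleleCounts, min_depth: int = 5) -> CpgAsmResult:
    """Two-sided Fisher exact test on (meth/unmeth) x (REF/ALT) at one CpG.

    Eligibility requires more than ``min_depth`` reads per allele; a
    zero-depth allele yields an ineligible result, not an error.
    """
    eligible = counts.depth_ref > min_depth and counts.depth_alt > min_depth
    if counts.depth_ref == 0 or counts.depth_alt == 0:
        return CpgAsmResult(counts.snp_id, counts.cpg_pos, 1.0, 0.0, False)
    table = [[counts.m_ref, counts.m_alt], [counts.u_ref, counts.u_alt]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    delta = counts.frac_ref - counts.frac_alt
    return CpgAsmResult(
        counts.snp_id, counts.cpg_pos, float(p), float(delta), eligible,
        frac_ref=counts.frac_ref, frac_alt=counts.frac_alt,
    )


def _wilcoxon_span(results, kind: str) -> float:
    ref = np.array([r.frac_ref for r in results])
    alt = np.array([r.frac_alt for r in results])
    if kind == "rank_sum":
        stat = stats.mannwhitneyu(ref, alt, alternative="two-sided")
        return float(stat.pvalue)
    diffs = ref - alt
    if np.allclose(diffs, 0):
        return 1.0
    # exact-conditional signed rank for small n, tie-corrected normal otherwise
    method = "exact" if len(diffs) <= 25 and not _has_ties(diffs) else "approx"
    try:
        res = stats.wilcoxon(ref, alt, zero_method="wilcox", method=method)
    except ValueError:
        return 1.0
    return float(res.pvalue)


def _has_ties(diffs) -> bool:
    nz = np.abs(diffs[diffs != 0])
    return len(np.unique(np.round(nz, 12))) < len(nz)


def _max_run(flags) -> int:
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def evaluate_window(results, *, fisher_alpha=0.05, min_asm_cpgs=3,
                    min_consecutive=2, min_mean_delta=0.20,
                    min_eligible=3, wilcoxon_kind="signed_rank"):
    """Apply the non-FDR DMR clauses to one (sample, SNP) window.

    ``results`` are per-CpG test results sorted by position.  Returns a
    dict describing the candidate (span, mean delta, Wilcoxon p, counts)
    or ``None`` when any clause fails.
    """
    elig = [r for r in sorted(results, key=lambda r: r.cpg_pos) if r.eligible]
    if len(elig) < min_eligible:
        return None
    asm_flags = [r.fisher_p < fisher_alpha for r in elig]
    n_asm = sum(asm_flags)
    if n_asm < min_asm_cpgs:
        return None
    if _max_run(asm_flags) < min_consecutive:
        return None
    asm_idx = [i for i, f in enumerate(asm_flags) if f]
    span = (elig[asm_idx[0]].cpg_pos, elig[asm_idx[-1]].cpg_pos)
    in_span = elig[asm_idx[0] : asm_idx[-1] + 1]
    mean_delta = float(np.mean([r.delta for r in in_span]))
    if abs(mean_delta) <= min_mean_delta + 1e-12:  # strictly > 20%
        return None
    return dict(
        snp_id=elig[0].snp_id,
        span=span,
        n_cpg_covered=len(elig),
        n_asm_cpg=n_asm,
        max_consecutive_asm=_max_run(asm_flags),
        mean_delta=mean_delta,
        wilcoxon_p=_wilcoxon_span(in_span, wilcoxon_kind),
    )


def call_asm_dmrs(windows: dict, sample_id: str, *, fisher_alpha=0.05,
                  min_asm_cpgs=3, min_consecutive=2, min_mean_delta=0.20,
                  min_eligible=3, dmr_fdr=0.05, wilcoxon_kind="signed_rank",
                  avg_coverage=None):
    """Call ASM DMRs for one sample.

    ``windows`` maps snp_id -> list of per-CpG results (see
    :func:`fisher_cpg`).  Candidate windows passing the count/contiguity/
    effect-size clauses enter one B-H family; DMRs are emitted at q <
    ``dmr_fdr``.  ``avg_coverage`` (snp_id -> mean per-allele read depth)
    is carried onto the DMRs for downstream ranking.
    """
    candidates = []
    for snp_id, results in windows.items():
        cand = evaluate_window(
            results, fisher_alpha=fisher_alpha, min_asm_cpgs=min_asm_cpgs,
            min_consecutive=min_consecutive, min_mean_delta=min_mean_delta,
            min_eligible=min_eligible, wilcoxon_kind=wilcoxon_kind,
        )
        if cand is not None:
            candidates.append(cand)
    if not candidates:
        return []
    pvals = [c["wilcoxon_p"] for c in candidates]
    reject, qvals, _, _ = multipletests(pvals, alpha=dmr_fdr, method="fdr_bh")
    dmrs = []
    for cand, rej, q in zip(candidates, reject, qvals):
        if not rej:
            continue
        cov = (avg_coverage or {}).get(cand["snp_id"], float("nan"))
        dmrs.append(
            AsmDmr(
                sample_id=sample_id, snp_id=cand["snp_id"], span=cand["span"],
                n_cpg_covered=cand["n_cpg_covered"], n_asm_cpg=cand["n_asm_cpg"],
                max_consecutive_asm=cand["max_consecutive_asm"],
                mean_delta=cand["mean_delta"], wilcoxon_p=cand["wilcoxon_p"],
                fdr_q=float(q), avg_allele_coverage=cov,
            )
        )
    return dmrs


def merge_dmrs(dmrs, cpg_results=None, merge_gap_bp: int = 250,
               wilcoxon_kind: str = "signed_rank"):
    """Merge overlapping or nearly adjacent (< ``merge_gap_bp`` intervening
    bp) DMRs within one sample; statistics are recomputed over the union
    span when the underlying per-CpG results are supplied.  Idempotent.
    """
    if not dmrs:
        return []
    dmrs = sorted(dmrs, key=lambda d: d.span)
    merged = [dmrs[0]]
    for d in dmrs[1:]:
        last = merged[-1]
        gap = d.span[0] - last.span[1] - 1
        if d.snp_id == last.snp_id and gap < merge_gap_bp:
            span = (last.span[0], max(last.span[1], d.span[1]))
            if cpg_results is not None:
                in_span = [
                    r for r in sorted(cpg_results.get(d.snp_id, []),
                                      key=lambda r: r.cpg_pos)
                    if r.eligible and span[0] <= r.cpg_pos <= span[1]
                ]
                mean_delta = float(np.mean([r.delta for r in in_span]))
                wilcoxon_p = _wilcoxon_span(in_span, wilcoxon_kind)
                n_cov = len(in_span)
                n_asm = sum(r.fisher_p < 0.05 for r in in_span)
                run = _max_run([r.fisher_p < 0.05 for r in in_span])
            else:
                w = np.array([last.n_cpg_covered, d.n_cpg_covered], dtype=float)
                mean_delta = float(
                    np.average([last.mean_delta, d.mean_delta], weights=w)
                )
                wilcoxon_p = min(last.wilcoxon_p, d.wilcoxon_p)
                n_cov = last.n_cpg_covered + d.n_cpg_covered
                n_asm = last.n_asm_cpg + d.n_asm_cpg
                run = max(last.max_consecutive_asm, d.max_consecutive_asm)
            merged[-1] = AsmDmr(
                sample_id=last.sample_id, snp_id=last.snp_id, span=span,
                n_cpg_covered=n_cov, n_asm_cpg=n_asm, max_consecutive_asm=run,
                mean_delta=mean_delta, wilcoxon_p=wilcoxon_p,
                fdr_q=min(last.fdr_q, d.fdr_q),
                avg_allele_coverage=np.nanmean(
                    [last.avg_allele_coverage, d.avg_allele_coverage]
                ),
            )
        else:
            merged.append(d)
    return merged


def bootstrap_asm_test(ref_meth, alt_meth, n_boot: int = 1000, k: int = 50,
                       seed: int = 0, min_depth: int = 100):
    """Bootstrap test for deep targeted bisulfite data.

    ``ref_meth``/``alt_meth`` are per-read fractional methylation vectors
    (>= ``min_depth`` reads per allele).  Each of ``n_boot`` resamples
    draws ``k`` reads per allele without replacement and applies a
    Wilcoxon rank-sum test; the median p across resamples is reported
    (mean and fraction < 0.05 are also returned).
    """
    ref_meth = np.asarray(ref_meth, dtype=float)
    alt_meth = np.asarray(alt_meth, dtype=float)
    if len(ref_meth) < min_depth or len(alt_meth) < min_depth:
        raise ValueError(
            f"bootstrap test requires >= {min_depth} reads per allele"
        )
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_boot)
    for b in range(n_boot):
        r = rng.choice(ref_meth, size=k, replace=False)
        a = rng.choice(alt_meth, size=k, replace=False)
        if np.all(r == r[0]) and np.all(a == a[0]) and r[0] == a[0]:
            pvals[b] = 1.0
            continue
        pvals[b] = stats.mannwhitneyu(r, a, alternative="two-sided").pvalue
    return dict(
        median_p=float(np.median(pvals)),
        mean_p=float(np.mean(pvals)),
        frac_significant=float(np.mean(pvals < 0.05)),
    )
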