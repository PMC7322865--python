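"""Cross-sample aggregation of ASM DMRs: recurrence, ranking, allele
switching, imprinting flags, normal vs cancer-only classification, and
per-sample summary statistics.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .types import CatalogEntry, SampleSummary


def aggregate_catalog(dmrs_by_sample: dict, informative_by_sample: dict,
                      min_recurrent: int = 2):
    """Build catalog entries keyed by index SNP.

    ``dmrs_by_sample`` maps sample_id -> [AsmDmr]; ``informative_by_sample``
    maps sample_id -> set of informative snp_ids.  Returns
    ``(recurrent, private)``: entries with ASM in >= ``min_recurrent``
    samples, and single-sample (private) entries kept for per-sample
    frequency statistics.
    """
    informative_counts: dict = {}
    for sample_id, snps in informative_by_sample.items():
        for snp_id in snps:
            informative_counts[snp_id] = informative_counts.get(snp_id, 0) + 1
    per_snp: dict = {}
    for sample_id, dmrs in dmrs_by_sample.items():
        best: dict = {}
        for d in dmrs:  # direction of the strongest segment at each SNP
            cur = best.get(d.snp_id)
            if cur is None or abs(d.mean_delta) > abs(cur.mean_delta):
                best[d.snp_id] = d
        for snp_id, d in best.items():
            per_snp.setdefault(snp_id, {})[sample_id] = d
    recurrent, private = [], []
    for snp_id in sorted(per_snp):
        samples = per_snp[snp_id]
        entry = CatalogEntry(
            snp_id=snp_id,
            n_informative_samples=informative_counts.get(snp_id, len(samples)),
            n_asm_samples=len(samples),
            asm_sample_ids={s: d.direction for s, d in samples.items()},
        )
        (recurrent if len(samples) >= min_recurrent else private).append(entry)
    return recurrent, private


def _dense_rank(scores, ids):
    """1 = best (highest score); ties broken by snp_id lexicographic."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], ids[i]))
    ranks = [0] * len(scores)
    for rank, i in enumerate(order, 1):
        ranks[i] = rank
    return ranks


def rank_loci(entries, dmrs_by_sample: dict):
    """Confidence/strength/overall ranking of catalog entries.

    confidence = geometric mean of (average per-allele coverage, number of
    ASM samples, percentage of ASM samples among informative samples);
    strength = geometric mean of (|methylation difference|, ASM CpG count,
    percentage of ASM CpGs among covered CpGs), each averaged across the
    ASM-positive samples.  Overall rank ranks the geometric mean of the
    two ranks.  A zero component gives score 0 (ranked last).
    """
    per_snp: dict = {}
    for sample_id, dmrs in dmrs_by_sample.items():
        for d in dmrs:
            per_snp.setdefault(d.snp_id, []).append(d)
    conf_scores, str_scores, ids = [], [], []
    for e in entries:
        dmrs = per_snp.get(e.snp_id, [])
        if not dmrs:
            conf_scores.append(0.0)
            str_scores.append(0.0)
            ids.append(e.snp_id)
            continue
        cov = np.nanmean([d.avg_allele_coverage for d in dmrs])
        if np.isnan(cov):
            cov = 0.0
        pct_samples = 100.0 * e.n_asm_samples / max(e.n_informative_samples, 1)
        conf = (max(cov, 0.0) * e.n_asm_samples * pct_samples) ** (1.0 / 3.0)
        mean_delta = np.mean([abs(d.mean_delta) for d in dmrs])
        n_asm = np.mean([d.n_asm_cpg for d in dmrs])
        pct_cpg = 100.0 * np.mean(
            [d.n_asm_cpg / max(d.n_cpg_covered, 1) for d in dmrs]
        )
        strength = (mean_delta * n_asm * pct_cpg) ** (1.0 / 3.0)
        conf_scores.append(float(conf))
        str_scores.append(float(strength))
        ids.append(e.snp_id)
    conf_ranks = _dense_rank(conf_scores, ids)
    str_ranks = _dense_rank(str_scores, ids)
    overall_key = [-np.sqrt(cr * sr) for cr, sr in zip(conf_ranks, str_ranks)]
    overall_ranks = _dense_rank(overall_key, ids)
    for e, cs, ss, cr, sr, orank in zip(
        entries, conf_scores, str_scores, conf_ranks, str_ranks, overall_ranks
    ):
        e.confidence_score = cs
        e.strength_score = ss
        e.confidence_rank = cr
        e.strength_rank = sr
        e.overall_rank = orank
    return entries


def switching_stats(entries, het_counts: dict, min_het_samples: int = 2):
    """Per-locus allele-switching fraction among ASM samples.

    Scored only for loci heterozygous in more than ``min_het_samples``
    samples (``het_counts``: snp_id -> number of heterozygous samples);
    otherwise the entry's switching fields stay ``None``.
    """
    for e in entries:
        if het_counts.get(e.snp_id, 0) <= min_het_samples:
            e.switching_fraction = None
            e.switch_flag = None
            continue
        dirs = list(e.asm_sample_ids.values())
        n_ref = sum(d == "REF_hyper" for d in dirs)
        minority = min(n_ref, len(dirs) - n_ref)
        e.switching_fraction = minority / len(dirs) if dirs else 0.0
        e.switch_flag = 0 < n_ref < len(dirs)
    return entries


def flag_imprinted(entries, snp_positions: dict, imprinted_tss,
                   sample_individuals: dict,
                   sample_cancer: dict | None = None, *,
                   window_bp: int = 150_000, min_individuals: int = 10,
                   min_switching: float = 0.20):
    """Flag known and candidate imprinted loci.

    ``imprinted_tss``: [(chrom, pos, gene)] of known imprinted-gene TSSs;
    loci inside a ``window_bp`` window centered on a TSS are flagged
    ``known``.  Loci outside the windows with ASM in more than
    ``min_individuals`` distinct (non-cancer, when status is supplied)
    individuals and switching fraction >= ``min_switching`` are flagged
    ``candidate``; everything else ``none``."""
    half = window_bp // 2
    tss_by_chrom: dict = {}
    for chrom, pos, _gene in imprinted_tss:
        tss_by_chrom.setdefault(chrom, []).append(pos)
    for e in entries:
        chrom, pos = snp_positions[e.snp_id]
        near = any(
            abs(pos - t) <= half for t in tss_by_chrom.get(chrom, [])
        )
        if near:
            e.imprint_flag = "known"
            continue
        asm_samples = e.asm_sample_ids
        if sample_cancer is not None:
            asm_samples = {
                s: d for s, d in asm_samples.items() if not sample_cancer.get(s, False)
            }
        individuals = {sample_individuals[s] for s in asm_samples}
        frac = e.switching_fraction
        if (
            len(individuals) > min_individuals
            and frac is not None
            and frac >= min_switching
        ):
            e.imprint_flag = "candidate"
        else:
            e.imprint_flag = "none"
    return entries


def classify_asm_class(entries, sample_cancer: dict):
    """cancer_only_ASM iff every ASM sample is cancer-class (the
    EBV-immortalized LCL counts as cancer); normal_ASM otherwise."""
    for e in entries:
        statuses = []
        for s in e.asm_sample_ids:
            if s not in sample_cancer:
                raise ValueError(f"sample {s} lacks a cancer/non-cancer label")
            statuses.append(sample_cancer[s])
        e.asm_class = "cancer_only_ASM" if statuses and all(statuses) else "normal_ASM"
    return entries


def sample_summaries(per_sample: dict):
    """Per-sample ASM frequency vs global methylation statistics.

    ``per_sample`` maps sample_id to a dict with keys ``cancer`` (bool),
    ``global_meth`` (mean fractional methylation over covered CpGs),
    ``n_asm`` and ``n_informative``.  Returns (summaries, stats_dict) with
    Spearman correlation, a linear model of frequency on methylation and
    cancer status, and the cancer/normal fold difference with a rank-sum
    test.  Degenerate inputs yield None statistics.
    """
    summaries = [
        SampleSummary(
            sample_id=s,
            cancer=bool(d["cancer"]),
            global_mean_methylation=float(d["global_meth"]),
            asm_frequency=(d["n_asm"] / d["n_informative"]) if d["n_informative"] else 0.0,
        )
        for s, d in sorted(per_sample.items())
    ]
    freq = np.array([s.asm_frequency for s in summaries])
    meth = np.array([s.global_mean_methylation for s in summaries])
    cancer = np.array([s.cancer for s in summaries], dtype=float)
    out = dict(rho=None, rho_p=None, beta_meth_p=None, beta_cancer_p=None,
               fold=None, fold_p=None)
    if len(summaries) >= 3 and np.ptp(freq) > 0 and np.ptp(meth) > 0:
        rho, p = stats.spearmanr(freq, meth)
        out["rho"], out["rho_p"] = float(rho), float(p)
        X = sm.add_constant(np.column_stack([meth, cancer]))
        fit = sm.OLS(freq, X).fit()
        out["beta_meth_p"] = float(fit.pvalues[1])
        out["beta_cancer_p"] = float(fit.pvalues[2])
    if cancer.any() and (~cancer.astype(bool)).any():
        fc = freq[cancer == 1]
        fn = freq[cancer == 0]
        if fn.mean() > 0:
            out["fold"] = float(fc.mean() / fn.mean())
        if np.ptp(freq) > 0:
            out["fold_p"] = float(
                stats.mannwhitneyu(fc, fn, alternative="two-sided").pvalue
            )
    return summaries, out
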