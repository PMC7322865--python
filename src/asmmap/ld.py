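"""Pairwise linkage disequilibrium, Gabriel haplotype blocks, and GWAS
colocalization of ASM index SNPs.

D' confidence bounds follow the Gabriel/Wall-Pritchard convention: a 90%
interval from the profile likelihood of |D'| on the multinomial two-locus
haplotype likelihood (grid step 0.001).  Blocks: pairs are classified as
strong LD / strong recombination / uninformative against mode-specific
CI thresholds; a block requires strong LD at its outermost pair and a
minimum fraction of strong pairs among informative pairs.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .types import HaploBlock, LdStats

GRID = np.linspace(0.0, 1.0, 1001)  # |D'| grid, step 0.001

STRINGENT = dict(ci_low=0.70, ci_high=0.98, recomb_high=0.90,
                 informative_frac=0.95, max_span=None)
LENIENT = dict(ci_low=0.60, ci_high=0.84, recomb_high=0.90,
               informative_frac=0.55, max_span=200_000)


def _hap_freqs(hap_a, hap_b):
    hap_a = np.asarray(hap_a)
    hap_b = np.asarray(hap_b)
    n = len(hap_a)
    n11 = int(((hap_a == 1) & (hap_b == 1)).sum())
    n10 = int(((hap_a == 1) & (hap_b == 0)).sum())
    n01 = int(((hap_a == 0) & (hap_b == 1)).sum())
    n00 = n - n11 - n10 - n01
    return np.array([n11, n10, n01, n00]), n


def dprime_ci(counts, alpha: float = 0.10):
    """90% profile-likelihood interval for |D'| from haplotype counts
    (n_AB, n_Ab, n_aB, n_ab)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    p_a = (counts[0] + counts[1]) / n
    p_b = (counts[0] + counts[2]) / n
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return None
    d_obs = counts[0] / n - p_a * p_b
    if d_obs >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    if d_max <= 0:
        return None
    sign = 1.0 if d_obs >= 0 else -1.0
    d_grid = sign * GRID * d_max
    f11 = np.clip(p_a * p_b + d_grid, 1e-12, 1.0)
    f10 = np.clip(p_a * (1 - p_b) - d_grid, 1e-12, 1.0)
    f01 = np.clip((1 - p_a) * p_b - d_grid, 1e-12, 1.0)
    f00 = np.clip((1 - p_a) * (1 - p_b) + d_grid, 1e-12, 1.0)
    ll = (
        counts[0] * np.log(f11) + counts[1] * np.log(f10)
        + counts[2] * np.log(f01) + counts[3] * np.log(f00)
    )
    like = np.exp(ll - ll.max())
    cdf = np.cumsum(like) / like.sum()
    low = float(GRID[np.searchsorted(cdf, alpha / 2)])
    high = float(GRID[min(np.searchsorted(cdf, 1 - alpha / 2), len(GRID) - 1)])
    return low, high


def compute_ld(hap_a, hap_b, snp_a: str = "A", snp_b: str = "B"):
    """LD statistics from two phased 0/1 haplotype vectors.

    Returns ``None`` for monomorphic input.  D = p_AB - p_A p_B;
    D' = |D| / D_max; r^2 = D^2 / (p_A p_a p_B p_b).
    """
    counts, n = _hap_freqs(hap_a, hap_b)
    p_a = (counts[0] + counts[1]) / n
    p_b = (counts[0] + counts[2]) / n
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return None
    p_ab = counts[0] / n
    d = p_ab - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    ci = dprime_ci(counts)
    lo, hi = ci if ci is not None else (0.0, 1.0)
    return LdStats(snp_a, snp_b, float(d), float(min(d_prime, 1.0)),
                   float(min(r2, 1.0)), lo, hi)


def _classify_pair(ci, mode_params):
    if ci is None:
        return "uninformative"
    lo, hi = ci
    if lo >= mode_params["ci_low"] and hi >= mode_params["ci_high"]:
        return "strong"
    if hi < mode_params["recomb_high"]:
        return "recomb"
    return "uninformative"


def gabriel_blocks(positions, haplotypes, snp_ids=None, mode: str = "stringent",
                   chrom: str = "chrS", max_pair_dist: int = 500_000):
    """Gabriel-style haplotype blocks from a phased panel.

    ``positions`` must be sorted ascending; ``haplotypes`` is
    (n_snps, n_haplotypes) of 0/1.  ``mode`` picks the stringent or
    lenient parameter set.  Maximal non-overlapping blocks are returned,
    longest span first during selection.
    """
    positions = list(positions)
    if positions != sorted(positions):
        raise ValueError("SNPs must be sorted by position")
    params = {"stringent": STRINGENT, "lenient": LENIENT}[mode]
    haplotypes = np.asarray(haplotypes)
    m = len(positions)
    snp_ids = snp_ids or [f"snp{i}" for i in range(m)]
    cls = {}
    for i in range(m):
        for j in range(i + 1, m):
            if positions[j] - positions[i] > max_pair_dist:
                break
            stats = compute_ld(haplotypes[i], haplotypes[j])
            ci = None if stats is None else (stats.ci_low, stats.ci_high)
            cls[(i, j)] = _classify_pair(ci, params)

    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            if (i, j) not in cls:
                continue
            span = positions[j] - positions[i]
            if params["max_span"] is not None and span > params["max_span"]:
                continue
            if cls[(i, j)] != "strong":
                continue
            n_strong = n_recomb = 0
            for a in range(i, j + 1):
                for b in range(a + 1, j + 1):
                    c = cls.get((a, b))
                    if c == "strong":
                        n_strong += 1
                    elif c == "recomb":
                        n_recomb += 1
            informative = n_strong + n_recomb
            if informative == 0:
                continue
            if n_strong / informative >= params["informative_frac"]:
                candidates.append((span, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    used = np.zeros(m, dtype=bool)
    blocks = []
    for span, i, j in candidates:
        if used[i : j + 1].any():
            continue
        used[i : j + 1] = True
        blocks.append(
            HaploBlock(chrom=chrom, start=positions[i], end=positions[j] + 1,
                       snp_ids=list(snp_ids[i : j + 1]), mode=mode)
        )
    blocks.sort(key=lambda b: b.start)
    return blocks


def colocalize_gwas(asm_positions: dict, gwas: pd.DataFrame, panel_snps,
                    haplotypes, blocks_by_mode: dict | None = None, *,
                    p_max: float = 1e-6, max_dist: int = 200_000,
                    r2_min: float = 0.8):
    """Colocalization flags per ASM index SNP against a GWAS catalog.

    ``asm_positions``: snp_id -> (chrom, pos).  GWAS rows above ``p_max``
    are dropped.  Flags: ``coincides`` (same position), ``r2_high``
    (r^2 > ``r2_min`` within ``max_dist``), and per-mode block
    co-membership.  GWAS SNPs absent from the panel leave r^2 unscored
    but still count for coincidence and block membership.
    """
    gwas = gwas[gwas["p"] < p_max]
    panel_idx = {s.snp_id: i for i, s in enumerate(panel_snps)}
    panel_pos = {}
    for i, s in enumerate(panel_snps):
        panel_pos.setdefault((s.chrom, s.pos), i)
    blocks_by_mode = blocks_by_mode or {}
    rows = []
    for snp_id, (chrom, pos) in asm_positions.items():
        coincides, r2_high = False, False
        best_r2 = None
        traits = []
        for _, g in gwas.iterrows():
            if g["chrom"] != chrom or abs(int(g["pos"]) - pos) > max_dist:
                continue
            traits.append(str(g["trait"]))
            if int(g["pos"]) == pos:
                coincides = True
            gi = panel_idx.get(str(g["snp_id"]))
            if gi is None:
                gi = panel_pos.get((g["chrom"], int(g["pos"])))
            ai = panel_idx.get(snp_id)
            if gi is not None and ai is not None:
                stats = compute_ld(haplotypes[ai], haplotypes[gi])
                if stats is not None:
                    best_r2 = max(best_r2 or 0.0, stats.r2)
                    if stats.r2 > r2_min:
                        r2_high = True
        block_flags = {}
        for mode, blocks in blocks_by_mode.items():
            hit = False
            for b in blocks:
                if snp_id in b.snp_ids:
                    for _, g in gwas.iterrows():
                        if g["chrom"] == b.chrom and b.start <= int(g["pos"]) < b.end:
                            hit = True
                            break
                if hit:
                    break
            block_flags[f"{mode}_block"] = hit
        rows.append(
            dict(snp_id=snp_id, coincides=coincides, r2_high=r2_high,
                 best_r2=best_r2, traits=sorted(set(traits)), **block_flags)
        )
    return pd.DataFrame(rows)


def gwas_enrichment(asm_snps, informative_background, flags: dict):
    """Enrichment of a colocalization flag among ASM SNPs; delegates to
    the annotation module's logistic machinery."""
    from .annotation import feature_enrichment

    if not any(flags.values()):
        return None
    return feature_enrichment(asm_snps, informative_background, flags)
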