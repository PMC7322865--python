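"""Read- and SNP-level filters and per-CpG per-allele count extraction.

Implements the quality-control chain applied before ASM calling: removal
of reads with poor bisulfite conversion, protocol-specific positional
masking of CpG calls, allele assignment with discard of discordant pairs
and of bisulfite-confounded strands, Hardy-Weinberg exact testing of
candidate SNPs, informative-SNP selection, and extraction of 2x2
methylation counts per CpG within a window centered on each index SNP.
"""
from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
from intervaltree import IntervalTree
from statsmodels.stats.multitest import multipletests

from .types import (
    ALT,
    AMBIG,
    PROTOCOLS,
    REF,
    AlleleRead,
    ConfigurationError,
    CpGAlleleCounts,
    IndexSnp,
)

# positional CpG-call masks per library protocol:
# {protocol: [(mate or None for both, from_5prime_bp, from_3prime_bp)]}
PROTOCOL_MASKS = {
    "SureSelect": [],
    "Nextera": [(2, 10, 0), (1, 0, 2), (2, 0, 2)],
    "TruSeq": [(1, 10, 0), (2, 10, 0), (2, 0, 2)],
    "ACCEL": [(2, 10, 0)],
}


def _mask_offsets(read: AlleleRead, masks):
    """CpG calls surviving the positional masks of the read's protocol."""
    kept = []
    for pos, meth in read.cpg_calls:
        if read.strand == "+":
            off5 = pos - read.start
        else:
            off5 = (read.start + read.length - 1) - pos
        off3 = read.length - 1 - off5
        masked = False
        for mate, n5, n3 in masks:
            if mate is not None and read.mate != mate:
                continue
            if off5 < n5 or off3 < n3:
                masked = True
                break
        if not masked:
            kept.append((pos, meth))
    return kept


def filter_reads(reads, protocol: str, max_ch_frac: float = 0.10):
    """Drop reads with > ``max_ch_frac`` unconverted CH cytosines and mask
    protocol-specific read ends (masked CpG calls are dropped, the read is
    retained).  Idempotent."""
    if protocol not in PROTOCOLS:
        raise ConfigurationError(f"unknown protocol {protocol!r}; use one of {PROTOCOLS}")
    masks = PROTOCOL_MASKS[protocol]
    out = []
    for read in reads:
        if read.ch_total > 0 and read.ch_unconverted / read.ch_total > max_ch_frac:
            continue
        calls = _mask_offsets(read, masks) if masks else list(read.cpg_calls)
        out.append(replace(read, cpg_calls=calls))
    return out


def assign_allele(read_group, snp: IndexSnp, mode: str = "SureSelect"):
    """Resolve the allele of one read (or read pair, given as a list of
    mates sharing a read_id).

    Returns the allele label or ``None`` when the read must be excluded:
    discordant mate calls (AMBIG), bisulfite-confounded strand for C/T
    (and, in WGBS mode, G/A) SNPs, or G/A SNPs wholesale in SureSelect
    mode.  Raises if the reads do not belong to ``snp``.
    """
    if isinstance(read_group, AlleleRead):
        read_group = [read_group]
    if any(r.snp_id != snp.snp_id for r in read_group):
        raise ValueError("read does not overlap the index SNP")
    cls = snp.snp_class
    if cls == "G/A" and mode == "SureSelect":
        return None  # SNP excluded wholesale upstream; defensive here
    calls = {r.allele for r in read_group if r.allele != AMBIG}
    if len(calls) > 1 or AMBIG in {r.allele for r in read_group}:
        return AMBIG
    # bisulfite-confounded strand: C/T SNPs unreadable on the C/T (+) strand,
    # G/A SNPs unreadable on the G/A (-) strand
    strand = read_group[0].strand
    if cls == "C/T" and strand == "+":
        return None
    if cls == "G/A" and mode == "WGBS" and strand == "-":
        return None
    return calls.pop() if calls else None


def resolve_pairs(reads, snp: IndexSnp, mode: str = "SureSelect"):
    """Group mates by read_id, apply :func:`assign_allele`, and return
    retained reads relabelled with their resolved allele (AMBIG pairs and
    strand-excluded reads discarded)."""
    by_id: dict = {}
    for r in reads:
        by_id.setdefault(r.read_id, []).append(r)
    out = []
    for rid, group in by_id.items():
        allele = assign_allele(group, snp, mode=mode)
        if allele in (REF, ALT):
            out.extend(replace(r, allele=allele) for r in group)
    return out


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test: sum of probabilities of all heterozygote
    counts (same parity, fixed allele counts) no more likely than observed.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("negative genotype count")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotypes")
    n_a = 2 * n_aa + n_ab  # minor-allele labelling is irrelevant to the test
    lgamma = math.lgamma

    def log_prob(nab):
        naa = (n_a - nab) // 2
        nbb = n - naa - nab
        return (
            lgamma(n + 1) - lgamma(naa + 1) - lgamma(nab + 1) - lgamma(nbb + 1)
            + nab * math.log(2.0)
            + lgamma(n_a + 1) + lgamma(2 * n - n_a + 1) - lgamma(2 * n + 1)
        )

    nab_values = [
        k for k in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    ]
    logs = np.array([log_prob(k) for k in nab_values])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[nab_values.index(n_ab)]
    return float(min(probs[probs <= obs * (1 + 1e-12)].sum(), 1.0))


def blacklist_tree(intervals) -> IntervalTree:
    tree = IntervalTree()
    for chrom, start, end, *_ in intervals:
        if end > start:
            tree[start:end] = chrom
    return tree


def informative_snps(
    snps,
    allele_depths: dict,
    sample_id: str,
    blacklist=None,
    *,
    min_reads_per_allele: int = 5,
    max_total_coverage: int = 200,
    hwe_fdr: float = 0.05,
    secondary_maf_max: float = 0.05,
):
    """Informative subset of candidate SNPs for one sample.

    ``allele_depths`` maps snp_id -> (ref_depth, alt_depth) in this sample.
    Retained SNPs are heterozygous in the sample, biallelic (secondary
    minor-allele frequency <= ``secondary_maf_max``), covered by at least
    ``min_reads_per_allele`` reads per allele and at most
    ``max_total_coverage`` in total, outside blacklist intervals, and pass
    a cohort-level Hardy-Weinberg exact test at B-H FDR >= ``hwe_fdr``
    (the B-H family is all candidate SNPs of the run).
    """
    tree = blacklist if isinstance(blacklist, IntervalTree) else blacklist_tree(blacklist or [])
    candidates = []
    for snp in snps:
        counts = [0, 0, 0]
        for g in snp.genotypes.values():
            counts[g] += 1
        candidates.append(hwe_exact_test(counts[0], counts[1], counts[2]))
    if candidates:
        reject, _, _, _ = multipletests(candidates, alpha=hwe_fdr, method="fdr_bh")
    else:
        reject = []
    out = []
    for snp, hwe_reject in zip(snps, reject):
        if snp.genotypes.get(sample_id) != 1:
            continue
        if hwe_reject:
            continue
        if snp.secondary_maf > secondary_maf_max:
            continue
        depth = allele_depths.get(snp.snp_id)
        if depth is None:
            continue
        ref_d, alt_d = depth
        if min(ref_d, alt_d) < min_reads_per_allele:
            continue
        if ref_d + alt_d > max_total_coverage:
            continue
        if tree.overlaps(snp.pos, snp.pos + 1):
            continue
        out.append(snp)
    return out


def allele_depths_from_reads(reads) -> dict:
    """Per-SNP (ref, alt) read-pair depths from allele-resolved reads."""
    depths: dict = {}
    seen: set = set()
    for r in reads:
        key = (r.snp_id, r.read_id)
        if key in seen or r.allele not in (REF, ALT):
            continue
        seen.add(key)
        d = depths.setdefault(r.snp_id, [0, 0])
        d[0 if r.allele == REF else 1] += 1
    return {k: tuple(v) for k, v in depths.items()}


def cpg_allele_counts(reads, snp: IndexSnp, common_snp_positions=(),
                      window_bp: int = 2000):
    """Per-CpG 2x2 methylation counts within the window centered on the SNP.

    Emits one record per CpG covered by at least one read on each allele.
    CpGs destroyed by common SNPs are flagged and excluded from downstream
    testing (the flag is carried on the record).
    """
    half = window_bp // 2
    lo, hi = snp.pos - half, snp.pos + half
    destroyed = set(common_snp_positions)
    acc: dict = {}
    for r in reads:
        if r.allele not in (REF, ALT):
            continue
        for pos, meth in r.cpg_calls:
            if not lo <= pos < hi:
                continue
            cell = acc.setdefault(pos, [0, 0, 0, 0])  # m_ref u_ref m_alt u_alt
            idx = (0 if meth else 1) + (0 if r.allele == REF else 2)
            cell[idx] += 1
    out = []
    for pos in sorted(acc):
        m_ref, u_ref, m_alt, u_alt = acc[pos]
        if (m_ref + u_ref) == 0 or (m_alt + u_alt) == 0:
            continue
        out.append(
            CpGAlleleCounts(
                snp_id=snp.snp_id, cpg_pos=pos, m_ref=m_ref, u_ref=u_ref,
                m_alt=m_alt, u_alt=u_alt,
                destroyed_by_common_snp=pos in destroyed,
            )
        )
    return out
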