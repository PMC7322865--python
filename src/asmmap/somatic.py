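"""Somatic mutation filtering in tumor/normal pairs, de novo ASM calling
around retained mutations, and motif-disruption enrichment among de novo
ASM mutations.
"""
from __future__ import annotations

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .calling import call_asm_dmrs, fisher_cpg
from .extraction import cpg_allele_counts
from .types import IndexSnp, SomaticMutation


def filter_somatic(tumor_variants, normal_variants, dbsnp_positions=(),
                   blacklist=(), min_depth_per_allele: int = 10):
    """Candidate somatic mutations of one tumor/normal pair.

    ``tumor_variants``/``normal_variants``: dicts with keys ``mut_id``,
    ``chrom``, ``pos``, ``ref``, ``alt``, ``depth_ref``, ``depth_alt``.
    Retained iff absent from dbSNP, outside blacklist intervals, absent
    from the matched normal, and covered by >= ``min_depth_per_allele``
    reads on each allele.  Order-independent and idempotent.
    """
    if normal_variants is None:
        raise ValueError("matched normal sample required for somatic filtering")
    normal_keys = {(v["chrom"], v["pos"]) for v in normal_variants}
    dbsnp = set(dbsnp_positions)
    tree = IntervalTree()
    for chrom, start, end, *_ in blacklist:
        if end > start:
            tree[start:end] = chrom
    out = []
    for v in sorted(tumor_variants, key=lambda v: (v["chrom"], v["pos"])):
        if v["pos"] in dbsnp:
            continue
        if (v["chrom"], v["pos"]) in normal_keys:
            continue
        if tree.overlaps(v["pos"], v["pos"] + 1):
            continue
        if min(v["depth_ref"], v["depth_alt"]) < min_depth_per_allele:
            continue
        mut = SomaticMutation(
            chrom=v["chrom"], pos=v["pos"], ref=v["ref"], alt=v["alt"],
            depth_ref=v["depth_ref"], depth_alt=v["depth_alt"],
            sample_id=v.get("sample_id", ""),
        )
        mut.mut_id = v.get("mut_id", f"{mut.chrom}:{mut.pos}")
        out.append(mut)
    return out


def call_denovo_asm(mutations, reads, sample_id: str, known_asm_positions,
                    *, exclusion_bp: int = 1000, window_bp: int = 2000,
                    per_cpg_min_depth: int = 5, **caller_kwargs):
    """De novo ASM calls around somatic mutations.

    Runs the standard DMR caller with each mutation as index variant
    (reads must carry the mutation id as ``snp_id``), then drops
    mutations within ``exclusion_bp`` (strict) of a known ASM index SNP:
    those may merely uncover germline ASM.  Returns
    ``(denovo_dmrs, n_tested, n_excluded)``.
    """
    known = sorted(int(p) for p in known_asm_positions)
    reads_by_mut: dict = {}
    for r in reads:
        reads_by_mut.setdefault(r.snp_id, []).append(r)
    windows = {}
    n_excluded = 0
    for mut in mutations:
        dists = [abs(mut.pos - p) for p in known]
        mut.dist_to_known_asm = min(dists) if dists else None
        if mut.dist_to_known_asm is not None and mut.dist_to_known_asm < exclusion_bp:
            n_excluded += 1
            continue
        mut_id = getattr(mut, "mut_id", f"{mut.chrom}:{mut.pos}")
        mreads = reads_by_mut.get(mut_id)
        if not mreads:
            continue
        snp = IndexSnp(
            snp_id=mreads[0].snp_id, chrom=mut.chrom, pos=mut.pos,
            ref=mut.ref, alt=mut.alt,
        )
        counts = cpg_allele_counts(mreads, snp, window_bp=window_bp)
        windows[snp.snp_id] = [
            fisher_cpg(c, min_depth=per_cpg_min_depth)
            for c in counts
            if not c.destroyed_by_common_snp
        ]
    dmrs = call_asm_dmrs(windows, sample_id, **caller_kwargs)
    return dmrs, len(windows), n_excluded


def denovo_motif_enrichment(denovo_disrupted: dict, nonasm_disrupted: dict,
                            n_denovo: int, n_nonasm: int,
                            germline_enriched=(), *, or_min: float = 2.0,
                            p_max: float = 0.05):
    """Per-motif enrichment among de novo ASM mutations and the overlap
    of enriched motif classes with the germline ASM-enriched set.

    ``denovo_disrupted``/``nonasm_disrupted`` map motif_id -> number of
    mutations disrupting or creating the motif in each mutation set
    (either allele direction).  Returns ``(per_motif_df_rows, overlap)``.
    """
    if n_denovo == 0 or n_nonasm == 0:
        raise ValueError("both mutation sets must be non-empty")
    motifs = sorted(set(denovo_disrupted) | set(nonasm_disrupted))
    rows = []
    for m in motifs:
        a = denovo_disrupted.get(m, 0)
        c = nonasm_disrupted.get(m, 0)
        table = [[a, n_denovo - a], [c, n_nonasm - c]]
        odds, p = stats.fisher_exact(table)
        if not np.isfinite(odds):
            odds = ((a + 0.5) * (n_nonasm - c + 0.5)) / (
                (n_denovo - a + 0.5) * (c + 0.5)
            )
        rows.append(dict(motif_id=m, odds_ratio=float(odds), p=float(p),
                         enriched=bool(odds > or_min and p < p_max)))
    enriched = {r["motif_id"] for r in rows if r["enriched"]}
    germline = set(germline_enriched)
    universe = set(motifs) | germline
    a = len(enriched & germline)
    b = len(enriched - germline)
    c = len(germline - enriched)
    d = len(universe - enriched - germline)
    odds, p = stats.fisher_exact([[a, b], [c, d]])
    overlap = dict(
        n_enriched=len(enriched),
        n_shared=a,
        shared_fraction=(a / len(enriched)) if enriched else None,
        odds_ratio=float(odds) if np.isfinite(odds) else float("inf"),
        p=float(p),
    )
    return rows, overlap
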