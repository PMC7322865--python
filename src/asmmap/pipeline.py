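"""End-to-end pipeline driver on a simulated cohort.

Stages: simulate -> extract/call per sample -> cross-sample catalog ->
motif mechanism tests -> cancer class models -> annotation/enrichment ->
LD + GWAS colocalization -> somatic de novo ASM.  Every stage writes its
tables under the output directory; a JSON run log records thresholds and
file checksums.  Deterministic under a fixed seed.

The default PWM panel is deliberately small (two motifs) so that each
motif accrues more than the minimum number of disrupted occurrences the
correlation analysis requires at desk scale — mirroring the published
per-motif occurrence filter rather than the published motif-panel size.
"""
from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as aio
from .annotation import (
    annotate_deserts,
    differential_enrichment,
    feature_enrichment,
    intersect_annotations,
)
from .calling import call_asm_dmrs, fisher_cpg, merge_dmrs
from .catalog import (
    aggregate_catalog,
    classify_asm_class,
    flag_imprinted,
    rank_loci,
    sample_summaries,
    switching_stats,
)
from .class_models import baseline_class_enrichment, classify_lom_gom
from .config import PipelineConfig, SimConfig
from .extraction import (
    allele_depths_from_reads,
    cpg_allele_counts,
    filter_reads,
    informative_snps,
    resolve_pairs,
)
from .ld import colocalize_gwas, gabriel_blocks
from .motifs import (
    call_disruptive,
    cpg_adjusted_correlation,
    motif_asm_correlation,
    motif_enrichment,
    sample_background,
    score_snps,
)
from .simulate import (
    make_default_pwms,
    simulate_annotations_and_panel,
    simulate_cohort,
    simulate_motif_landscape,
    simulate_reads,
    write_fixtures,
)
from .somatic import call_denovo_asm, denovo_motif_enrichment, filter_somatic
from .types import ConfigurationError, IndexSnp


@dataclass
class PipelineResult:
    outdir: str
    catalog: list = field(default_factory=list)
    private: list = field(default_factory=list)
    summaries: list = field(default_factory=list)
    summary_stats: dict = field(default_factory=dict)
    dmrs_by_sample: dict = field(default_factory=dict)
    informative_by_sample: dict = field(default_factory=dict)
    occurrences: list = field(default_factory=list)
    enrichment: pd.DataFrame | None = None
    correlation: pd.DataFrame | None = None
    lomgom: dict = field(default_factory=dict)
    annotations: dict = field(default_factory=dict)
    feature_tables: dict = field(default_factory=dict)
    blocks: dict = field(default_factory=dict)
    colocalization: pd.DataFrame | None = None
    somatic: dict = field(default_factory=dict)
    truth = None
    cohort = None


def _snp_from_locus(locus, genotypes):
    return IndexSnp(
        snp_id=locus.snp_id, chrom=locus.chrom, pos=locus.pos,
        ref=locus.ref, alt=locus.alt, genotypes=genotypes[locus.snp_id],
        maf=locus.maf,
    )


def process_sample(sample_id, reads, snps, pipe: PipelineConfig, blacklist=()):
    """Run extraction + DMR calling for one sample.

    Returns a dict with the informative SNP set, per-window CpG results,
    merged DMRs, and global methylation summary.
    """
    reads = filter_reads(reads, pipe.protocol, pipe.max_ch_unconverted_frac)
    by_snp: dict = {}
    for r in reads:
        by_snp.setdefault(r.snp_id, []).append(r)
    snp_by_id = {s.snp_id: s for s in snps}
    resolved: dict = {}
    for snp_id, snp_reads in by_snp.items():
        snp = snp_by_id.get(snp_id)
        if snp is None:
            continue
        mode = "WGBS" if pipe.wgbs_mode else "SureSelect"
        resolved[snp_id] = resolve_pairs(snp_reads, snp, mode=mode)
    all_resolved = [r for rs in resolved.values() for r in rs]
    depths = allele_depths_from_reads(all_resolved)
    informative = informative_snps(
        snps, depths, sample_id, blacklist,
        min_reads_per_allele=pipe.min_reads_per_allele,
        max_total_coverage=pipe.max_total_coverage,
        hwe_fdr=pipe.hwe_fdr, secondary_maf_max=pipe.secondary_maf_max,
    )
    windows, meth_sum, call_sum = {}, 0, 0
    avg_cov = {}
    for snp in informative:
        counts = cpg_allele_counts(
            resolved.get(snp.snp_id, []), snp, window_bp=pipe.window_bp
        )
        results = [
            fisher_cpg(c, min_depth=pipe.per_cpg_min_depth)
            for c in counts
            if not c.destroyed_by_common_snp
        ]
        windows[snp.snp_id] = results
        for c in counts:
            meth_sum += c.m_ref + c.m_alt
            call_sum += c.depth_ref + c.depth_alt
        d = depths.get(snp.snp_id, (0, 0))
        avg_cov[snp.snp_id] = (d[0] + d[1]) / 2.0
    dmrs = call_asm_dmrs(
        windows, sample_id, fisher_alpha=pipe.cpg_fisher_alpha,
        min_asm_cpgs=pipe.min_asm_cpgs, min_consecutive=pipe.min_consecutive_asm,
        min_mean_delta=pipe.min_mean_delta, min_eligible=pipe.min_eligible_cpgs,
        dmr_fdr=pipe.dmr_fdr, wilcoxon_kind=pipe.wilcoxon_kind,
        avg_coverage=avg_cov,
    )
    dmrs = merge_dmrs(dmrs, windows, merge_gap_bp=pipe.merge_gap_bp,
                      wilcoxon_kind=pipe.wilcoxon_kind)
    return dict(
        informative={s.snp_id for s in informative},
        windows=windows,
        dmrs=dmrs,
        global_meth=(meth_sum / call_sum) if call_sum else float("nan"),
    )


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_asm_track(entries, snp_positions: dict, path) -> None:
    """Browser-style BED6 detail track: one record per index SNP, name
    encoding rank / ASM class / imprint flag / switching."""
    rows = []
    n = max((e.overall_rank for e in entries), default=1)
    for e in sorted(entries, key=lambda e: snp_positions[e.snp_id][1]):
        chrom, pos = snp_positions[e.snp_id]
        name = (
            f"{e.snp_id}|rank={e.overall_rank}|class={e.asm_class}"
            f"|imprint={e.imprint_flag}"
            f"|switch={'NA' if e.switching_fraction is None else round(e.switching_fraction, 3)}"
        )
        score = int(round(1000 * (n - e.overall_rank + 1) / n))
        rows.append((chrom, pos, pos + 1, name, score, "."))
    aio.write_bed(rows, path)


def run_pipeline(sim: SimConfig, pipe: PipelineConfig, outdir: str,
                 n_pwms: int = 2, stages=None) -> PipelineResult:
    """Run the full pipeline on a simulated cohort; write all outputs
    under ``outdir`` and return the in-memory result bundle."""
    all_stages = ("simulate", "call", "catalog", "motif", "models",
                  "annotate", "ld", "somatic")
    stages = set(all_stages if stages is None else stages)
    unknown = stages - set(all_stages)
    if unknown:
        raise ConfigurationError(f"unknown pipeline stages: {sorted(unknown)}")
    os.makedirs(outdir, exist_ok=True)
    res = PipelineResult(outdir=outdir)
    log = dict(seed=sim.seed, thresholds=pipe.to_dict(), stages=sorted(stages),
               files={})

    # ---- simulate -------------------------------------------------------
    cohort, truth = simulate_cohort(sim)
    pwms = make_default_pwms(n=n_pwms, seed=sim.seed)
    windows = simulate_motif_landscape(cohort, truth, pwms)
    reads = simulate_reads(cohort, truth)
    bundle = simulate_annotations_and_panel(cohort, truth, pwms)
    res.cohort, res.truth = cohort, truth
    if "simulate" in stages:
        fixdir = os.path.join(outdir, "fixtures")
        write_fixtures(cohort, truth, fixdir, reads=reads, windows=windows,
                       pwms=pwms, bundle=bundle)
    snps = [_snp_from_locus(l, cohort.genotypes) for l in cohort.loci]
    snp_positions = {l.snp_id: (l.chrom, l.pos) for l in cohort.loci}

    # ---- per-sample extraction + calling -------------------------------
    sample_meta = {
        s.sample_id: dict(cancer=s.cancer, individual=s.individual_id,
                          cell_type=s.cell_type, matched=s.matched_normal)
        for s in cohort.samples
    }
    per_sample_windows = {}
    per_sample_info = {}
    if "call" in stages:
        for s in cohort.samples:
            out = process_sample(
                s.sample_id, reads[s.sample_id], snps, pipe, bundle.blacklist
            )
            res.dmrs_by_sample[s.sample_id] = out["dmrs"]
            res.informative_by_sample[s.sample_id] = out["informative"]
            per_sample_windows[s.sample_id] = out["windows"]
            per_sample_info[s.sample_id] = out

    # ---- catalog --------------------------------------------------------
    if "catalog" in stages and res.dmrs_by_sample:
        recurrent, private = aggregate_catalog(
            res.dmrs_by_sample, res.informative_by_sample,
            min_recurrent=pipe.min_recurrent_samples,
        )
        rank_loci(recurrent, res.dmrs_by_sample)
        het_counts = {
            l.snp_id: sum(g == 1 for g in cohort.genotypes[l.snp_id].values())
            for l in cohort.loci
        }
        switching_stats(recurrent, het_counts, pipe.switching_min_het_samples)
        flag_imprinted(
            recurrent, snp_positions, bundle.imprinted_tss,
            {s: m["individual"] for s, m in sample_meta.items()},
            {s: m["cancer"] for s, m in sample_meta.items()},
            window_bp=pipe.imprint_window_bp,
            min_individuals=pipe.imprint_min_individuals,
            min_switching=pipe.imprint_min_switching,
        )
        classify_asm_class(recurrent, {s: m["cancer"] for s, m in sample_meta.items()})
        res.catalog, res.private = recurrent, private
        per_sample = {}
        asm_by_sample: dict = {}
        for sample_id, dmrs in res.dmrs_by_sample.items():
            asm_by_sample[sample_id] = {d.snp_id for d in dmrs}
        for sample_id, meta in sample_meta.items():
            info = per_sample_info.get(sample_id)
            if info is None:
                continue
            per_sample[sample_id] = dict(
                cancer=meta["cancer"], global_meth=info["global_meth"],
                n_asm=len(asm_by_sample.get(sample_id, ())),
                n_informative=len(info["informative"]),
            )
        res.summaries, res.summary_stats = sample_summaries(per_sample)

    # catalog-derived sets used by later stages (known imprinted removed)
    genotype_catalog = [e for e in res.catalog if e.imprint_flag != "known"]
    asm_snp_ids = {e.snp_id for e in genotype_catalog}
    informative_union = set().union(*res.informative_by_sample.values()) if res.informative_by_sample else set()

    # ---- motif mechanism ------------------------------------------------
    if "motif" in stages:
        # the ASM set and the sampled background are scored as separate
        # test families, as when estimating the random expectation of
        # motif disruption from a background SNP sample
        background = sample_background(
            informative_union - asm_snp_ids, len(asm_snp_ids),
            ratio=pipe.background_ratio, cap=pipe.background_cap, seed=pipe.seed,
        )
        asm_occ = score_snps(
            {k: w for k, w in windows.items() if k in asm_snp_ids}, pwms
        )
        bg_occ = score_snps(
            {k: w for k, w in windows.items() if k in background}, pwms
        )
        delta_by_snp: dict = {}
        for sample_id, dmrs in res.dmrs_by_sample.items():
            for d in dmrs:
                delta_by_snp.setdefault(d.snp_id, []).append(d.mean_delta)
        for o in asm_occ:
            if o.snp_id in delta_by_snp:
                o.mean_delta_meth = float(np.mean(delta_by_snp[o.snp_id]))
        occurrences = asm_occ + bg_occ
        res.occurrences = occurrences
        disrupted = call_disruptive(
            occurrences, q_max=pipe.disruption_q, p_binding=pipe.binding_p
        )
        disrupted_by_motif: dict = {}
        for o in disrupted:
            disrupted_by_motif.setdefault(o.motif_id, set()).add(o.snp_id)
        res.enrichment = motif_enrichment(
            disrupted_by_motif, asm_snp_ids, background,
            or_min=pipe.enrichment_or, q_max=pipe.enrichment_q,
            min_occurrences=1,
        )
        asm_disrupted = [o for o in disrupted if o.snp_id in asm_snp_ids]
        res.correlation = motif_asm_correlation(
            asm_disrupted, min_occurrences=pipe.min_disrupted_occurrences,
            fdr=pipe.correlation_fdr, r2_min=pipe.correlation_r2,
        )
        if res.correlation is not None and not res.correlation.empty:
            adj = {}
            for motif_id in res.correlation["motif_id"]:
                occ = [o for o in asm_disrupted if o.motif_id == motif_id]
                adj[motif_id] = cpg_adjusted_correlation(occ)
            res.correlation = res.correlation.assign(
                adjusted_slope=[
                    (adj[m] or {}).get("slope") for m in res.correlation["motif_id"]
                ]
            )

    # ---- cancer class models -------------------------------------------
    if "models" in stages and res.catalog:
        res.lomgom = _lom_gom_stage(
            res, cohort, truth, sample_meta, per_sample_windows, pipe
        )

    # ---- annotation -----------------------------------------------------
    if "annotate" in stages:
        ann = intersect_annotations(
            snp_positions, bundle.dnase, bundle.states,
            small_window_bp=pipe.small_window_bp,
        )
        annotate_deserts(ann, pipe.desert_max_dnase, pipe.strong_states)
        res.annotations = ann
        feature_tables = {}
        states = sorted({st for a in ann.values() for st in a.states})
        for state in states + ["desert"]:
            flags = {
                s: (a.desert if state == "desert" else state in a.states)
                for s, a in ann.items()
            }
            feature_tables[state] = feature_enrichment(
                asm_snp_ids, sorted(informative_union), flags
            )
            cancer_only = {
                e.snp_id for e in genotype_catalog if e.asm_class == "cancer_only_ASM"
            }
            if cancer_only and (asm_snp_ids - cancer_only):
                try:
                    feature_tables[f"{state}_differential"] = differential_enrichment(
                        sorted(informative_union),
                        {s: s in asm_snp_ids for s in informative_union},
                        {s: s in cancer_only for s in informative_union},
                        flags,
                    )
                except ValueError:
                    pass
        res.feature_tables = feature_tables

    # ---- LD + GWAS ------------------------------------------------------
    if "ld" in stages:
        order = np.argsort([s.pos for s in bundle.panel_snps], kind="stable")
        panel_snps = [bundle.panel_snps[i] for i in order]
        haps = bundle.haplotypes[order]
        positions = [s.pos for s in panel_snps]
        ids = [s.snp_id for s in panel_snps]
        blocks = {
            mode: gabriel_blocks(positions, haps, ids, mode=mode,
                                 max_pair_dist=12_000)
            for mode in ("stringent", "lenient")
        }
        res.blocks = blocks
        asm_positions = {
            e.snp_id: snp_positions[e.snp_id] for e in genotype_catalog
        }
        res.colocalization = colocalize_gwas(
            asm_positions, bundle.gwas, panel_snps, haps, blocks,
            p_max=pipe.gwas_p_max, max_dist=pipe.ld_max_dist,
            r2_min=pipe.r2_high,
        )

    # ---- somatic --------------------------------------------------------
    if "somatic" in stages:
        res.somatic = _somatic_stage(res, bundle, pwms, snp_positions, pipe)

    _write_outputs(res, snp_positions, log)
    return res


def _lom_gom_stage(res, cohort, truth, sample_meta, per_sample_windows, pipe):
    """Raw-mean allele configurations at cancer-only loci with matched
    normals, LOM/GOM classification, and baseline-class enrichment."""
    from .class_models import fit_allele_level_model

    cancer_only = [e for e in res.catalog if e.asm_class == "cancer_only_ASM"]
    rows, configs = [], {}
    for e in cancer_only:
        for sample_id in e.asm_sample_ids:
            meta = sample_meta[sample_id]
            matched = meta.get("matched")
            if not matched:
                continue
            cw = per_sample_windows.get(sample_id, {}).get(e.snp_id)
            nw = per_sample_windows.get(matched, {}).get(e.snp_id)
            if not cw or not nw:
                continue

            def allele_means(results):
                ref = np.nanmean([r.frac_ref for r in results if r.eligible])
                alt = np.nanmean([r.frac_alt for r in results if r.eligible])
                return ref, alt

            c_means = allele_means(cw)
            n_means = allele_means(nw)
            if any(np.isnan(v) for v in (*c_means, *n_means)):
                continue
            configs[(e.snp_id, sample_id)] = (n_means, c_means)
            for cell_type, means in (("normal", n_means), ("cancer", c_means)):
                lo, hi = sorted(means)
                rows.append(dict(snp_id=e.snp_id, cell_type=cell_type,
                                 allele_rank="low", meth=lo))
                rows.append(dict(snp_id=e.snp_id, cell_type=cell_type,
                                 allele_rank="high", meth=hi))
    out = dict(n_pairs=len(configs))
    classes = {}
    for key, (n_means, c_means) in configs.items():
        classes[key] = classify_lom_gom(
            n_means, c_means, pipe.meth_low, pipe.meth_high
        )
    out["classes"] = classes
    labels = list(classes.values())
    out["n_lom"] = labels.count("LOM")
    out["n_gom"] = labels.count("GOM")
    df = pd.DataFrame(rows)
    if not df.empty and df["snp_id"].nunique() >= pipe.min_model_loci:
        means, _fit = fit_allele_level_model(df, min_loci=pipe.min_model_loci)
        out["model_means"] = means
    # baseline (normal-sample) methylation classes at cancer-only loci
    target, background = [], []
    for snp_id, per in truth.allele_means.items():
        normal_mu = np.mean(
            [np.mean(per[s]) for s, m in sample_meta.items() if not m["cancer"]]
        )
        background.append(normal_mu)
        if snp_id in {e.snp_id for e in cancer_only}:
            target.append(normal_mu)
    if target:
        out["baseline_enrichment"] = baseline_class_enrichment(
            target, background, pipe.meth_low, pipe.meth_high
        )
    return out


def _somatic_stage(res, bundle, pwms, snp_positions, pipe):
    from .motifs import score_snps as _score

    known_positions = [snp_positions[e.snp_id][1] for e in res.catalog]
    out = {}
    germline_enriched = set()
    if res.enrichment is not None and not res.enrichment.empty:
        germline_enriched = set(
            res.enrichment.loc[res.enrichment["enriched"], "motif_id"]
        )
    for sample_id, variants in bundle.somatic_variants.items():
        normals = [v for v in variants if v["in_normal"] or v["in_dbsnp"]]
        muts = filter_somatic(
            variants, normals, bundle.dbsnp_positions, bundle.blacklist,
            min_depth_per_allele=pipe.somatic_min_depth_per_allele,
        )
        dmrs, n_tested, n_excluded = call_denovo_asm(
            muts, bundle.somatic_reads[sample_id], sample_id, known_positions,
            exclusion_bp=pipe.denovo_exclusion_bp, window_bp=pipe.window_bp,
            per_cpg_min_depth=pipe.per_cpg_min_depth,
            fisher_alpha=pipe.cpg_fisher_alpha, min_asm_cpgs=pipe.min_asm_cpgs,
            min_consecutive=pipe.min_consecutive_asm,
            min_mean_delta=pipe.min_mean_delta,
            min_eligible=pipe.min_eligible_cpgs, dmr_fdr=pipe.dmr_fdr,
            wilcoxon_kind=pipe.wilcoxon_kind,
        )
        denovo_ids = {d.snp_id for d in dmrs}
        windows = {
            mid: w for mid, w in bundle.somatic_windows.items()
            if any(v["mut_id"] == mid for v in variants)
        }
        occ = _score(windows, pwms)
        denovo_disrupted: dict = {}
        nonasm_disrupted: dict = {}
        from .motifs import call_disruptive as _disr

        for o in _disr(occ, q_max=pipe.disruption_q, p_binding=pipe.binding_p):
            target = denovo_disrupted if o.snp_id in denovo_ids else nonasm_disrupted
            target[o.motif_id] = target.get(o.motif_id, 0) + 1
        n_denovo = len(denovo_ids)
        n_nonasm = max(n_tested - n_denovo, 0)
        entry = dict(
            n_candidates=len(muts), n_tested=n_tested, n_excluded=n_excluded,
            n_denovo=n_denovo,
            denovo_fraction=(n_denovo / n_tested) if n_tested else None,
        )
        if n_denovo and n_nonasm:
            per_motif, overlap = denovo_motif_enrichment(
                denovo_disrupted, nonasm_disrupted, n_denovo, n_nonasm,
                germline_enriched, or_min=pipe.denovo_or, p_max=pipe.denovo_p,
            )
            entry["motif_enrichment"] = per_motif
            entry["germline_overlap"] = overlap
        out[sample_id] = entry
    return out


def _write_outputs(res: PipelineResult, snp_positions, log) -> None:
    outdir = res.outdir
    cat_rows = []
    for e in res.catalog:
        chrom, pos = snp_positions[e.snp_id]
        cat_rows.append(
            dict(
                snp_id=e.snp_id, chrom=chrom, pos=pos,
                n_informative=e.n_informative_samples,
                n_asm=e.n_asm_samples,
                confidence_rank=e.confidence_rank, strength_rank=e.strength_rank,
                overall_rank=e.overall_rank,
                switching_fraction=e.switching_fraction,
                asm_class=e.asm_class, imprint_flag=e.imprint_flag,
            )
        )
    pd.DataFrame(cat_rows).to_csv(
        os.path.join(outdir, "catalog.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        [
            dict(sample_id=s.sample_id, cancer=s.cancer,
                 global_mean_methylation=round(s.global_mean_methylation, 6),
                 asm_frequency=round(s.asm_frequency, 6))
            for s in res.summaries
        ]
    ).to_csv(os.path.join(outdir, "sample_summaries.tsv"), sep="\t", index=False)
    if res.enrichment is not None:
        res.enrichment.to_csv(
            os.path.join(outdir, "motif_enrichment.tsv"), sep="\t", index=False
        )
    if res.correlation is not None:
        res.correlation.to_csv(
            os.path.join(outdir, "motif_correlation.tsv"), sep="\t", index=False
        )
    if res.colocalization is not None:
        coloc = res.colocalization.copy()
        if "traits" in coloc:
            coloc["traits"] = coloc["traits"].map(lambda t: ",".join(t))
        coloc.to_csv(
            os.path.join(outdir, "gwas_colocalization.tsv"), sep="\t", index=False
        )
    if res.catalog:
        write_asm_track(
            res.catalog, snp_positions, os.path.join(outdir, "asm_track.bed")
        )
    for name in ("catalog.tsv", "sample_summaries.tsv", "motif_enrichment.tsv",
                 "motif_correlation.tsv", "gwas_colocalization.tsv",
                 "asm_track.bed"):
        path = os.path.join(outdir, name)
        if os.path.exists(path):
            log["files"][name] = _sha256(path)
    with open(os.path.join(outdir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True, default=str)
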