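"""Serialize a simulated cohort to disk in the external interface formats."""
from __future__ import annotations

import os

from .. import io as aio
from ..pwm import write_jaspar

SOMATIC_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=ADR,Number=1,Type=Integer,Description="Ref allele depth">\n'
    '##INFO=<ID=ADA,Number=1,Type=Integer,Description="Alt allele depth">\n'
    "##contig=<ID=chrS,length=100000000>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_somatic_vcf(variants, path, normal: bool = False) -> None:
    """Tumor VCF carries every candidate; the matched-normal VCF carries
    only variants genuinely present in the normal sample."""
    rows = [v for v in variants if v["in_normal"] or v["in_dbsnp"]] if normal else variants
    with open(path, "w") as fh:
        fh.write(SOMATIC_HEADER)
        for v in sorted(rows, key=lambda v: v["pos"]):
            fh.write(
                f"{v['chrom']}\t{v['pos'] + 1}\t{v['mut_id']}\t{v['ref']}\t{v['alt']}"
                f"\t.\tPASS\tADR={v['depth_ref']};ADA={v['depth_alt']}\n"
            )


def read_somatic_vcf(path):
    import pysam

    out = []
    for rec in pysam.VariantFile(path):
        out.append(
            dict(
                mut_id=rec.id, chrom=rec.chrom, pos=rec.pos - 1, ref=rec.ref,
                alt=rec.alts[0], depth_ref=int(rec.info.get("ADR", 0)),
                depth_alt=int(rec.info.get("ADA", 0)),
            )
        )
    return out


def write_fixtures(cohort, truth, outdir, reads=None, windows=None, pwms=None,
                   bundle=None) -> dict:
    """Write every available fixture under ``outdir``; returns the path map.

    Round-tripping any written file through its reader reproduces the
    in-memory objects exactly.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    aio.write_snps_vcf(cohort.loci, cohort.genotypes, cohort.sample_ids, p("snps.vcf"))
    aio.write_truth_json(truth, p("truth.json"))
    if reads is not None:
        rd = os.path.join(outdir, "reads")
        os.makedirs(rd, exist_ok=True)
        for sample_id, sample_reads in reads.items():
            path = os.path.join(rd, f"{sample_id}.tsv")
            paths[f"reads/{sample_id}.tsv"] = path
            aio.write_reads_tsv(sample_reads, path)
    if windows is not None:
        aio.write_windows_fasta(windows, p("windows.fa"))
    if pwms is not None:
        write_jaspar(pwms, p("pwms.jaspar"))
    if bundle is not None:
        aio.write_bed(bundle.dnase, p("dnase.bed"))
        aio.write_bed(bundle.states, p("states.bed"))
        aio.write_bed(bundle.blacklist, p("blacklist.bed"))
        aio.write_bed(
            [(c, pos, pos + 1, gene) for c, pos, gene in bundle.imprinted_tss],
            p("imprinted_tss.bed"),
        )
        aio.write_panel_vcf(bundle.panel_snps, bundle.haplotypes, p("panel.vcf"))
        aio.write_gwas_tsv(bundle.gwas, p("gwas.tsv"))
        with open(p("dbsnp_positions.txt"), "w") as fh:
            for pos in sorted(bundle.dbsnp_positions):
                fh.write(f"{pos}\n")
        som = os.path.join(outdir, "somatic")
        os.makedirs(som, exist_ok=True)
        for sample_id, variants in bundle.somatic_variants.items():
            tpath = os.path.join(som, f"{sample_id}_tumor.vcf")
            npath = os.path.join(som, f"{sample_id}_normal.vcf")
            paths[f"somatic/{sample_id}_tumor.vcf"] = tpath
            paths[f"somatic/{sample_id}_normal.vcf"] = npath
            write_somatic_vcf(variants, tpath, normal=False)
            write_somatic_vcf(variants, npath, normal=True)
            rpath = os.path.join(som, f"{sample_id}_reads.tsv")
            paths[f"somatic/{sample_id}_reads.tsv"] = rpath
            aio.write_reads_tsv(bundle.somatic_reads[sample_id], rpath)
        if bundle.somatic_windows:
            aio.write_windows_fasta(bundle.somatic_windows, p("somatic_windows.fa"))
    return paths
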