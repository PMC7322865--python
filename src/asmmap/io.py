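"""Readers and writers for the pipeline's external formats.

VCF v4.2 (index SNPs, phased panel, somatic calls; read back via pysam),
BED3/6 (0-based half-open), reads tables (TSV, one row per CpG call),
GWAS catalog TSV, truth-table JSON, and FASTA windows (read via pyfaidx
when available).  Strict parsing: format violations raise
:class:`~asmmap.types.FormatError` with a line number.
"""
from __future__ import annotations

import json
import os

import pandas as pd
import pysam

from .pwm import SnpWindow
from .types import AlleleRead, FormatError, IndexSnp

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID={contig},length={length}>\n"
)

READS_COLUMNS = [
    "read_id", "mate", "strand", "allele", "snp_id", "cpg_pos", "meth",
    "ch_total", "ch_unconverted", "start", "length", "protocol",
]


def _open_out(path):
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    return open(path, "w")


# -- SNP / genotype VCF ---------------------------------------------------


def write_snps_vcf(loci, genotypes, sample_ids, path, contig="chrS",
                   contig_len=100_000_000) -> None:
    """Index-SNP VCF with per-sample unphased genotypes (ALT dosage)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with _open_out(path) as fh:
        fh.write(VCF_HEADER.format(contig=contig, length=contig_len))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for locus in sorted(loci, key=lambda l: (l.chrom, l.pos)):
            gts = "\t".join(
                gt_map[genotypes[locus.snp_id][s]] for s in sample_ids
            )
            fh.write(
                f"{locus.chrom}\t{locus.pos + 1}\t{locus.snp_id}\t{locus.ref}"
                f"\t{locus.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_snps_vcf(path):
    """Parse an index-SNP VCF into IndexSnp records (0-based positions)."""
    try:
        vcf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    snps = []
    for rec in vcf.fetch() if vcf.index is not None else vcf:
        if rec.alts is None or len(rec.alts) != 1:
            raise FormatError(f"{path}: {rec.id}: not biallelic")
        genotypes = {}
        for sample, call in rec.samples.items():
            gt = call.get("GT")
            if gt is None or None in gt:
                raise FormatError(f"{path}: {rec.id}: missing GT for {sample}")
            genotypes[sample] = int(sum(gt))
        snps.append(
            IndexSnp(
                snp_id=rec.id, chrom=rec.chrom, pos=rec.pos - 1,
                ref=rec.ref, alt=rec.alts[0], genotypes=genotypes,
            )
        )
    return snps


# -- phased panel VCF -----------------------------------------------------


def write_panel_vcf(panel_snps, haplotypes, path, contig="chrS",
                    contig_len=100_000_000) -> None:
    """Phased haplotype panel; haplotypes is (n_snps, 2N) of 0/1."""
    n_ind = haplotypes.shape[1] // 2
    sample_ids = [f"ind_P{i+1:04d}" for i in range(n_ind)]
    order = sorted(range(len(panel_snps)), key=lambda i: panel_snps[i].pos)
    with _open_out(path) as fh:
        fh.write(VCF_HEADER.format(contig=contig, length=contig_len))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for i in order:
            s = panel_snps[i]
            row = haplotypes[i]
            gts = "\t".join(
                f"{row[2*j]}|{row[2*j+1]}" for j in range(n_ind)
            )
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t{s.snp_id}\t{s.ref}\t{s.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_panel_vcf(path):
    """Parse a phased panel VCF.  Returns (snps, haplotypes) where snps is
    a list of ``(snp_id, chrom, pos, ref, alt)`` and haplotypes is a list of
    0/1 rows.  Unphased genotypes raise FormatError naming the GT field."""
    import numpy as np

    try:
        vcf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    snps, rows = [], []
    for rec in vcf:
        hap = []
        for sample, call in rec.samples.items():
            if not call.phased:
                raise FormatError(
                    f"{path}: {rec.id}: GT for {sample} is not phased ('|' required)"
                )
            hap.extend(int(a) for a in call["GT"])
        snps.append((rec.id, rec.chrom, rec.pos - 1, rec.ref, rec.alts[0]))
        rows.append(hap)
    return snps, np.array(rows, dtype=np.int8)


# -- BED ------------------------------------------------------------------


def write_bed(intervals, path) -> None:
    """Write BED3+ rows (tuples beyond 3 fields are emitted as-is)."""
    with _open_out(path) as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path, min_fields: int = 3):
    """Parse BED; returns tuples (chrom, start, end, *rest).  Half-open,
    0-based.  Malformed lines raise FormatError with the line number."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < min_fields:
                raise FormatError(f"{path}:{ln}: expected >= {min_fields} fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinates") from exc
            if end < start:
                raise FormatError(f"{path}:{ln}: end < start")
            out.append((parts[0], start, end, *parts[3:]))
    return out


# -- reads table ----------------------------------------------------------


def write_reads_tsv(reads, path) -> None:
    """One row per CpG call; reads without CpG calls get a sentinel row."""
    with _open_out(path) as fh:
        fh.write("\t".join(READS_COLUMNS) + "\n")
        for r in reads:
            base = (
                f"{r.read_id}\t{r.mate}\t{r.strand}\t{r.allele}\t{r.snp_id}"
            )
            tail = f"{r.ch_total}\t{r.ch_unconverted}\t{r.start}\t{r.length}\t{r.protocol}"
            if r.cpg_calls:
                for pos, meth in r.cpg_calls:
                    fh.write(f"{base}\t{pos}\t{meth}\t{tail}\n")
            else:
                fh.write(f"{base}\t-1\t0\t{tail}\n")


def read_reads_tsv(path):
    """Reconstruct AlleleRead objects from a reads table."""
    df = pd.read_csv(path, sep="\t")
    missing = set(READS_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    reads = []
    grouped = df.groupby(["read_id", "mate"], sort=False)
    for (rid, mate), grp in grouped:
        first = grp.iloc[0]
        calls = [
            (int(p), int(m))
            for p, m in zip(grp["cpg_pos"], grp["meth"])
            if p >= 0
        ]
        reads.append(
            AlleleRead(
                read_id=str(rid), mate=int(mate), strand=str(first["strand"]),
                allele=str(first["allele"]), snp_id=str(first["snp_id"]),
                cpg_calls=calls, ch_total=int(first["ch_total"]),
                ch_unconverted=int(first["ch_unconverted"]),
                protocol=str(first["protocol"]), start=int(first["start"]),
                length=int(first["length"]),
            )
        )
    return reads


# -- GWAS catalog ---------------------------------------------------------


def write_gwas_tsv(gwas: pd.DataFrame, path) -> None:
    gwas.to_csv(path, sep="\t", index=False)


def read_gwas_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"snp_id", "chrom", "pos", "trait", "p"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


# -- truth table JSON -----------------------------------------------------


def write_truth_json(truth, path) -> None:
    with _open_out(path) as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)


def read_truth_json(path):
    from .simulate.cohort import TruthTable

    with open(path) as fh:
        return TruthTable.from_json_dict(json.load(fh))


# -- SNP-window FASTA -----------------------------------------------------


def write_windows_fasta(windows, path) -> None:
    with _open_out(path) as fh:
        for w in windows.values():
            fh.write(f">{w.snp_id}|REF snp_index={w.snp_index}\n{w.seq_ref}\n")
            fh.write(f">{w.snp_id}|ALT snp_index={w.snp_index}\n{w.seq_alt}\n")


def read_windows_fasta(path):
    """Parse the paired REF/ALT window FASTA back into SnpWindow objects."""
    seqs, meta = {}, {}
    name = None
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if line.startswith(">"):
                head = line[1:].split()
                name = head[0]
                meta[name] = dict(kv.split("=") for kv in head[1:] if "=" in kv)
                seqs[name] = ""
            elif name is not None:
                seqs[name] += line
            elif line:
                raise FormatError(f"{path}:{ln}: sequence before header")
    windows = {}
    for key in seqs:
        if not key.endswith("|REF"):
            continue
        snp_id = key[:-4]
        alt_key = snp_id + "|ALT"
        if alt_key not in seqs:
            raise FormatError(f"{path}: missing ALT window for {snp_id}")
        windows[snp_id] = SnpWindow(
            snp_id, seqs[key], seqs[alt_key], int(meta[key].get("snp_index", 0))
        )
    return windows
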