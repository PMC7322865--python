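# asmmap

Allele-specific DNA methylation (ASM) mapping from allele-resolved
bisulfite sequencing data: calling of ASM differentially methylated
regions (DMRs), cross-sample cataloguing with imprinting and
allele-switching statistics, transcription-factor motif-disruption
mechanism tests, mixed-model characterization of cancer-associated
loss/gain of methylation (LOM/GOM), chromatin-desert annotation, and
haplotype-block colocalization with GWAS peaks.

## Who this is for

Groups analysing methyl-seq or WGBS cohorts in which reads have been
assigned to the two alleles of heterozygous "index" SNPs (e.g. Bismark +
BisSNP output). ASM mapping is a post-GWAS strategy: a DMR whose two
alleles differ systematically in CpG methylation flags a nearby
regulatory sequence variant (rSNP), and disruptive SNPs in CTCF and TF
binding motifs are the principal mechanism. The package implements the
full statistical chain on tabular inputs, and ships a synthetic-cohort
generator with known ground truth so that every stage is testable
without any sequencing data.

## The statistics at the core

Per CpG within a 2 kb window centered on a heterozygous index SNP, the
2×2 table of (methylated/unmethylated) × (REF/ALT) read counts is tested
with a two-sided Fisher exact test. A DMR is called in one sample when

* ≥ 3 CpGs have Fisher *p* < 0.05, including ≥ 2 consecutive CpGs,
* |mean Δmethylation| over covered CpGs in the span is > 20%, and
* a Wilcoxon signed-rank test across per-CpG allele-fraction pairs
  survives Benjamini–Hochberg correction (FDR < 0.05) over all
  candidate windows of the sample; DMRs < 250 bp apart are merged.

Upstream filters follow standard practice: reads with > 10% unconverted
CHG/CHH cytosines are dropped; protocol-specific read-end masks are
applied; discordant read pairs and bisulfite-confounded strands (C/T and
G/A SNPs) are excluded; informative SNPs are heterozygous, biallelic,
covered by ≥ 5 reads per allele and ≤ 200× total, outside blacklist
regions, and in Hardy–Weinberg equilibrium (exact test, B-H FDR).

Downstream, loci recurrent in ≥ 2 samples are ranked by geometric-mean
confidence and strength scores; allele switching and imprinting
(150 kb windows around known imprinted TSSs; > 10 individuals with
≥ 20% switching → candidate) are scored; allelic binding affinity is
scored per PWM with an exact convolution null for the best-hit score and
a paired empirical null for the allelic score difference (disruption:
*q* < 0.05 and binding *p* < 0.005); and per-motif ordinary least squares
relates allelic methylation differences to allelic affinity differences
(significant: FDR < 0.05, R² > 0.4). Cancer analyses use linear mixed
models (random intercept + slope) for allele-configuration estimation
and for ASM-class × affinity interactions. LD uses D′ with
profile-likelihood confidence intervals and Gabriel-style blocks under
stringent and lenient parameter sets; colocalization flags ASM SNPs
coinciding with or in strong LD (r² > 0.8 within 200 kb) with GWAS peaks
(*p* < 10⁻⁶).

## Worked example

```python
from asmmap.config import SimConfig, PipelineConfig
from asmmap.pipeline import run_pipeline

res = run_pipeline(SimConfig(seed=1), PipelineConfig(seed=1), "out/")
print(len(res.catalog), "recurrent ASM loci")
print("rho=%.2f  cancer/normal fold=%.2f"
      % (res.summary_stats["rho"], res.summary_stats["fold"]))
print(res.correlation[["motif_id", "slope", "r2", "q"]].round(4))
print("LOM", res.lomgom["n_lom"], "GOM", res.lomgom["n_gom"])
```

prints (seed 1):

```
72 recurrent ASM loci
rho=-0.81  cancer/normal fold=1.61
   motif_id   slope     r2      q
CTCF_like_1 -0.0395 0.7423 0.0006
      TFM_1 -0.0391 0.5601 0.0033
LOM 37 GOM 9
```

Reading: the per-sample ASM frequency is anti-correlated with global
methylation (Spearman ρ = −0.81) and higher in the simulated cancers;
both planted motif classes show the inverse affinity→methylation
correlation (more disruptive allele → more methylated) at the planted
slope; and cancer-only ASM decomposes into allele-specific LOM at
baseline-hypermethylated loci plus a GOM minority in poised chromatin.
Outputs on disk: `catalog.tsv`, `sample_summaries.tsv`,
`motif_enrichment.tsv`, `motif_correlation.tsv`,
`gwas_colocalization.tsv`, a browser track `asm_track.bed`, the
serialized fixtures, and `run_log.json` with every threshold used and
output checksums. The same run is available from the shell:
`asmmap all --seed 1 --out out/`.

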