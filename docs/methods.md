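# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limits of the `asmmap` package.

## ASM calling model

Allele-resolved reads are the unit of input: each read (or mate) carries
an allele call at one heterozygous index SNP and a list of per-CpG
binary methylation calls. Conversion quality is controlled by dropping
reads with strictly more than 10% unconverted CHG/CHH cytosines.
Library-specific positional artefacts are removed by masking CpG calls
near read ends: Nextera — first 10 bp of mate 2's 5′ end and the last
2 bp of both mates' 3′ ends; TruSeq — first 10 bp of both 5′ ends and
the last 2 bp of mate 2's 3′ end; ACCEL — first 10 bp of mate 2's 5′
end; SureSelect — none. Offsets are measured from the 5′ end in read
orientation, so minus-strand reads are masked from their rightmost base.

Allele assignment discards read pairs whose mates disagree, excludes the
bisulfite-confounded strand for C/T SNPs (and for G/A SNPs in WGBS
mode), and excludes G/A SNPs wholesale in SureSelect mode, where only
the minus strand is captured.

Informative SNPs must be heterozygous in the sample, biallelic
(secondary minor-allele frequency ≤ 0.05), covered by at least 5 read
pairs per allele and at most 200× in total, outside blacklist
intervals, and must pass a cohort-level Hardy–Weinberg exact test at
B-H FDR ≥ 0.05. The HWE test enumerates all heterozygote counts of the
observed parity with fixed allele counts and sums the probabilities of
configurations no more likely than the observed one; the B-H family is
all candidate SNPs of one cohort run, using pooled cohort genotype
counts (the alternative — testing against an external panel — is not
implemented).

Per-CpG eligibility for testing requires strictly more than 5 reads per
allele; a CpG record is emitted whenever both alleles are covered at
all, keeping counting separate from testing. CpGs whose dinucleotide is
destroyed by a common SNP (maf > 0.05) are flagged and excluded from
tests. The DMR definition is the conjunction of four clauses (≥3
significant CpGs, ≥2 consecutive in the ordered list of covered eligible
CpGs, mean |Δmethylation| > 20% over the span between the first and
last significant CpG, B-H-corrected Wilcoxon q < 0.05). "Consecutive"
means adjacent in coverage order, not genomic adjacency. The Wilcoxon
test is the paired signed-rank across per-CpG allele-fraction pairs
(pairing by CpG is the natural structure; the rank-sum variant is
available by configuration), exact-conditional for n ≤ 25 without ties
and normal-approximated with tie correction otherwise. The B-H family
is the set of candidate windows (those passing the non-FDR clauses)
within one sample run. Merging joins DMRs separated by fewer than
250 intervening bp and recomputes statistics over the union span.

For deep targeted validation data (≥100 reads per allele) the bootstrap
test draws 50 reads per allele without replacement 1000 times and
applies a rank-sum test per draw; the median p over draws is reported
(mean and fraction < 0.05 are also emitted) since deep coverage would
otherwise drive p-values to zero. The choice of the median as the
aggregate is ours; the aggregation of the 1000 p-values is otherwise
unconstrained.

## Catalog, ranking, switching, imprinting

Loci with ASM in ≥ 2 samples form the recurrent catalog; single-sample
("private") calls are kept only for per-sample frequency statistics.
Confidence score = geometric mean of (average per-allele coverage,
number of ASM samples, percentage of ASM samples among informative
samples, on a 0–100 scale); strength score = geometric mean of (mean
|Δmethylation|, number of significant CpGs, percentage of significant
CpGs among covered CpGs), averaged across ASM-positive samples. Scores
map to ranks (1 = best; ties broken by SNP identifier), and the overall
rank ranks the geometric mean of the two ranks. Multi-segment loci take
the direction of their strongest segment.

Switching is scored for loci heterozygous in more than 2 samples as the
minority-direction fraction among ASM samples. Imprinting: loci within
150 kb windows centered on known imprinted TSSs are flagged `known` and
removed from the genotype-dependent catalog; outside those windows,
ASM in more than 10 distinct non-cancer individuals with switching
≥ 20% flags a `candidate`. Note that the expectation of the
minority-direction fraction of a fair coin over n samples is below 0.5
(about 0.40 at n = 15); tests compare against that binomial expectation
rather than against 0.5 itself.

## Motif scoring and the disruption test

PWMs are per-position base-probability matrices (JASPAR text, parsed
via Biopython) normalized with a pseudocount of 0.25 per column; scores
are log2 likelihood ratios against a uniform zero-order background.
For each index SNP, both allele windows are scored over every offset
and strand whose L-mer covers the SNP, and the best hit is kept.

Two nulls are used. (1) Best-hit significance: the single-offset score
distribution is computed exactly by column-wise convolution on a 1e-3
grid (with an L-bin conservative slack against rounding), and the best
over n alignments is approximated by a Šidák combination; this is exact
in the enumerable test regime and slightly conservative under
alignment dependence. (2) Allelic score difference: the two alleles
share their flanking sequence, so treating their scores as independent
draws produces a null far too wide — a genuinely disruptive SNP would
never reach significance. We therefore use a paired empirical null:
seeded background windows of length 2L−1 with the SNP at the center,
best hit computed per allele (the weaker allele's best hit may shift
alignment to dodge the substitution), two-sided p on |Δscore| with
add-one smoothing over 2000 draws, cached per motif. q-values are B-H
within the scored family; as in the published procedure, the ASM SNP
set and the sampled background set (3× the ASM count, capped at 40,000,
seeded) form separate families. Disruption requires q < 0.05 and
binding p < 0.005 on at least one allele. The enrichment default is
OR > 2 with q < 0.05 (the stricter of the two published variants; both
are exposed in the configuration).

Per-motif correlation of the average allelic methylation difference
(across ASM samples) with the allelic affinity difference uses OLS over
motifs with more than 10 disrupted occurrences; significance requires
B-H FDR < 0.05 and R² > 0.4; a negative slope is the inverse
(higher affinity → lower methylation) relation. The CpG adjustment
refits with a CpG-presence covariate when both strata have ≥ 3
occurrences.

## Cancer class models

At cancer-only ASM loci informative in both a cancer sample and its
lineage-matched normal, allele-rank (low/high) methylation is modelled
with a linear mixed model (fixed: rank × cell type; random intercept
and rank slope per locus; REML), refusing to fit below 10 loci.
LOM: both normal alleles above 0.7 and the low cancer allele at or
below 0.3 with the high allele still above 0.7; GOM: both normal
alleles below 0.3 and the high cancer allele at or above 0.7; the
0.3/0.7 class boundaries are configurable — the published description
names low/intermediate/high classes without numeric bounds, and a
symmetric split is the natural default. Classification is invariant to
allele label swap and is applied to raw per-locus means with the mixed
model supplying the cohort-average configuration.

The class-interaction model regresses the allelic methylation
difference on the affinity difference with ASM-class interaction
(2-class normal/cancer or 4-class × desert), random intercept + slope
per motif (REML; random-intercept fallback on non-convergence,
flagged), motifs filtered at ≥ 10 occurrences total and ≥ 3 per class;
per-class marginal slopes carry Bonferroni-corrected Wald p-values.

## Annotation, deserts, ASB

Interval work is half-open 0-based throughout (BED at the boundary;
VCF converts at I/O). A 1 kb window around each index SNP collects
DNase-positive track counts and the union of chromatin-state labels
over tracks. A chromatin desert has ≤ 1 DNase-positive track and no
strong state, with the strong vocabulary fixed to {active_promoter,
strong_enhancer, poised_promoter, poised_enhancer, insulator}.
Feature enrichment is bivariate logistic regression of ASM status
against the full informative background (Fisher/Haldane fallback under
separation, infinite OR reported when the feature is absent from the
background); differential enrichment adds the ASM × cancer-class
interaction. ASB calls use a two-sample Fisher test of ChIP allelic
counts against the WGBS allelic counts of the same SNP (controlling
allelic mapping bias, rather than testing against 50:50 or requiring a
fully homozygous ChIP genotype), B-H FDR < 0.05, at sites with > 10
ChIP reads; concordance (hypomethylated allele more occupied) is tested
with a one-sided exact binomial against 0.5.

## LD and GWAS colocalization

From phased haplotypes: D = p_AB − p_A·p_B, D′ = |D|/D_max,
r² = D²/(p_A p_a p_B p_b). The 90% D′ interval comes from the profile
likelihood of |D′| on the multinomial two-locus haplotype likelihood,
grid step 0.001 (5th/95th percentiles of the normalized likelihood).
Gabriel blocks classify pairs as strong LD (CI bounds ≥ 0.70/0.98
stringent, ≥ 0.60/0.84 lenient), strong recombination (upper bound
< 0.90), or uninformative; a block requires strong LD at its outer pair
and a strong fraction among informative pairs of ≥ 0.95 (stringent) or
≥ 0.55 (lenient), with lenient spans capped at 200 kb; maximal
non-overlapping blocks are chosen longest-first. Colocalization flags
ASM SNPs that coincide with, are in r² > 0.8 within 200 kb of, or share
a block with GWAS SNPs at p < 10⁻⁶. An EM haplotype-frequency step for
unphased panels is not implemented; the panel interface requires phase.

## Somatic de novo ASM

Candidate somatic mutations in a tumor/matched-normal pair must be
absent from dbSNP, the blacklist, and the matched normal, with ≥ 10
reads per allele. The standard DMR caller runs with each mutation as
index variant; calls within 1 kb (point-to-point, strict) of known ASM
index SNPs are excluded as potential uncovering of germline ASM. Motif
association counts both disruption (reference allele stronger) and
creation (mutant allele stronger); per-motif enrichment against
non-ASM mutations uses Fisher tests (enriched: OR > 2, p < 0.05), and
the enriched set is compared with the germline ASM-enriched motif
classes by a 2×2 overlap test.

## The synthetic cohort

The generator defines the study conditions. Defaults: 28 normal + 8
cancer samples (cell types cycled over T cell/B cell/glia/liver and
myeloma/lymphoma/GBM, cancers paired with lineage-matched normals),
120 index-SNP loci on one contig at 80 kb spacing (outside each other's
150 kb imprinting windows), 8 CpGs per locus, Poisson(20) truncated-≥1
read pairs per allele, allele frequency 0.5 with Hardy–Weinberg
genotypes. Locus classes are allocated deterministically by rounded
fractions: 25% genotype-dependent ASM, 10% imprinted, 5% switching,
20% cancer-only (70% LOM / 30% GOM), the rest null. Baseline
methylation is bimodal (Beta(2,12) / Beta(12,2), 65% high mode);
cancer samples lose 0.3 from high-methylation loci, emptying the > 0.8
mode. The ASM effect size is 0.4 (fractional-methylation difference);
genotype-ASM effects scale with the planted PWM score difference
(δ = 0.4·ΔPWM/8 bits), imprinted loci flip the hypermethylated parent
50:50 per individual, switching loci flip direction in 30% of
individuals, and cancer LOM/GOM move one allele to 0.20/0.75 with the
affected allele drawn per individual. 1% of reads carry conversion
failure, 2% are discordant pairs, one locus is over-covered (×15) and
two are blacklisted, to exercise the filters.

Each fragment covers every CpG of its locus, making per-CpG per-allele
methylated counts exactly Binomial(n_reads, μ) with truncated-Poisson
n_reads — the simplest model that exercises every downstream test.
There is no within-read correlation, no beta-binomial overdispersion,
no coverage bias, and no alignment error; passing tests therefore
demonstrate the statistical chain's correctness and calibration under
the stated model, not robustness to real-data artefacts.

Synthetic PWMs mimic the heterogeneous information profile of real
count matrices: one deepest "critical" contact column at the center
(minor-base frequencies 1%/0.5%/0.25%, with the deepest minors placed
on bases that are not bisulfite-confounded against the consensus),
moderately constrained cores, weak flanks, lengths 16–20. Disruptive
SNPs are planted at the critical column (substitutions to the two
deepest admissible minors), which makes the planted |Δscore| larger
than almost any single substitution a background window can realize
once the best hit may re-align — the property that gives the paired
difference null its power. Embedded occurrences draw their degenerate
positions from the motif model, so CpG presence varies between
occurrences of the same motif. The default pipeline panel holds two
motifs so each accrues more than the 10 disrupted occurrences the
correlation analysis requires at this cohort scale (the published
analysis applies the same per-motif floor to a much larger panel).

The haplotype panel uses block-wise founder copying: each locus owns a
block of 5 SNPs whose founder haplotypes are nested (allele = founder
index below a per-SNP threshold), guaranteeing pairwise D′ = 1 inside
blocks and free recombination between them; a GWAS proxy SNP sharing
the index SNP's threshold has an identical allele column, hence
r² = 1 exactly. 122 DNase pseudo-cell-type tracks and two
chromatin-state tracks implement deserts (≤ 1 DNase track, quiescent
everywhere) and poised-chromatin GOM loci by construction.

## Numerical choices and degenerate inputs

Seeding is hierarchical (seed + stage + sample/locus keys hashed with
crc32), so per-sample streams are independent of generation order and
runs are byte-identical under a fixed seed; all derived seeds stay
below 2³¹. Fisher tests use scipy's exact implementation (verified
against full hypergeometric enumeration for N ≤ 24 and sampled tables
to N = 40); a zero-depth allele yields an ineligible record, not an
error. Logistic fits fall back to Haldane-corrected 2×2 odds ratios
with Fisher p-values under separation. Degenerate summary inputs
(constant frequency vectors, empty methylation classes, monomorphic
SNPs) return null statistics rather than raising. Ranking treats a
zero component as score 0, ranked last.

## Problem sizes

The bundled experiments use desk-scale sizes chosen for tight
statistical checks: 500 null + 500 effect loci at coverage 50 per
allele for error-rate calibration, 20 motifs × 50 occurrences for
correlation-gate recovery, 60 motifs × 20 occurrences for the
interaction model, 400 panel haplotypes for block recovery, and the
36-sample × 120-locus cohort for the end-to-end run. Published
headline counts from 100+ deeply sequenced samples (tens of thousands
of DMRs, 5–9× cancer ASM excess) are not reproducible at this scale;
the corresponding checks are property-based (signs, calibrated error
rates, recovery of planted effects) rather than count-matching.

## Known limitations

- The binomial read model understates real overdispersion; effect-size
  recovery on real data will be noisier than the calibration suggests.
- The Šidák best-hit combination ignores overlap dependence between
  alignments (slightly conservative).
- The paired difference null is Monte-Carlo (resolution ~5e-4 at 2000
  draws); extremely small q-values are therefore bounded.
- Unphased panels are not supported (no EM haplotype estimator).
- The per-motif CpG adjustment degenerates when CpG presence is
  constant within a motif, and is skipped in that case.
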