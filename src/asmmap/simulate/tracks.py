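"""Annotation tracks, phased haplotype panel, GWAS catalog, and somatic
variants with known ground truth.

The haplotype panel uses block-wise founder copying: each locus owns a
block of SNPs whose founder haplotypes are nested (allele = founder index
below a per-SNP threshold), which guarantees pairwise D' = 1 inside a
block; founders are drawn independently across blocks, so blocks are
separated by free recombination.  A GWAS SNP planted with the same founder
threshold as the index SNP has an identical allele column, hence r^2 = 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..config import SimConfig, rng_for
from ..pwm import BASES, SnpWindow
from ..types import ALT, REF, AlleleRead
from .cohort import CHROM, Cohort, TruthTable
from .motifs import WINDOW, _random_seq

GWAS_TRAITS = (
    "ulcerative_colitis",
    "multiple_myeloma",
    "schizophrenia",
    "type_2_diabetes",
    "celiac_disease",
)

DENOVO_DELTA = 0.5
DENOVO_BASELINE = 0.55


@dataclass
class PanelSnp:
    snp_id: str
    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class AnnotationBundle:
    dnase: list = field(default_factory=list)  # (chrom, start, end, track)
    states: list = field(default_factory=list)  # (chrom, start, end, state, track)
    blacklist: list = field(default_factory=list)  # (chrom, start, end)
    imprinted_tss: list = field(default_factory=list)  # (chrom, pos, gene)
    panel_snps: list = field(default_factory=list)  # [PanelSnp]
    haplotypes: np.ndarray | None = None  # (n_snps, 2N) 0/1
    gwas: pd.DataFrame | None = None
    dbsnp_positions: set = field(default_factory=set)
    somatic_variants: dict = field(default_factory=dict)  # sample -> [dict]
    somatic_reads: dict = field(default_factory=dict)  # sample -> [AlleleRead]
    somatic_windows: dict = field(default_factory=dict)  # mut_id -> SnpWindow
    somatic_truth: dict = field(default_factory=dict)  # (sample, mut_id) -> label

    def panel_index(self):
        return {s.snp_id: i for i, s in enumerate(self.panel_snps)}


def _nested_founders(k: int, thresholds):
    """Founder haplotype matrix (n_snps, k); allele 1 iff founder < c_j."""
    return np.array([[1 if f < c else 0 for f in range(k)] for c in thresholds])


def _simulate_panel(cohort: Cohort, cfg: SimConfig, bundle: AnnotationBundle,
                    gwas_linked: set, rng) -> dict:
    """Build panel SNPs + haplotypes; returns {snp_id: column_index}."""
    n_hap = 2 * cfg.n_panel_individuals
    k = cfg.panel_founders_per_block
    offsets = np.linspace(-4000, 4000, cfg.panel_block_snps).astype(int)
    mid = cfg.panel_block_snps // 2
    snps, columns = [], []
    for locus in cohort.loci:
        founders = rng.integers(0, k, size=n_hap)
        thresholds = [(1 + (j % (k - 1))) for j in range(cfg.panel_block_snps)]
        thresholds[mid] = k // 2  # index SNP at intermediate frequency
        fmat = _nested_founders(k, thresholds)
        for j, off in enumerate(offsets):
            pos = locus.pos + int(off)
            if off == 0:
                snps.append(
                    PanelSnp(locus.snp_id, locus.chrom, pos, locus.ref, locus.alt)
                )
            else:
                snps.append(PanelSnp(f"{locus.snp_id}_b{j}", locus.chrom, pos, "A", "C"))
            columns.append(fmat[j][founders])
        if locus.snp_id in gwas_linked:
            # proxy SNP with the index SNP's threshold: identical column, r^2=1
            pos = locus.pos + 1500
            snps.append(PanelSnp(f"gw_{locus.snp_id}", locus.chrom, pos, "A", "C"))
            columns.append(fmat[mid][founders])
    bundle.panel_snps = snps
    bundle.haplotypes = np.array(columns, dtype=np.int8)
    return {s.snp_id: i for i, s in enumerate(snps)}


def _simulate_somatic(cohort: Cohort, truth: TruthTable, cfg: SimConfig,
                      bundle: AnnotationBundle, pwms) -> None:
    pairs = [s for s in cohort.samples if s.cancer and s.matched_normal]
    asm_loci = [l for l in cohort.loci if truth.locus_class[l.snp_id] == "genotype_ASM"]
    base = 5000 + cfg.n_loci * cfg.locus_spacing + 50_000
    for si, sample in enumerate(pairs):
        rng = rng_for(cfg.seed, "somatic", sample.sample_id)
        variants, reads = [], []
        mut_counter = 0

        def add_variant(pos, kind, depth=(15, 12), in_dbsnp=False, in_normal=False,
                        blacklisted=False):
            nonlocal mut_counter
            mut_id = f"mut_{sample.sample_id}_{mut_counter}"
            mut_counter += 1
            variants.append(
                dict(
                    mut_id=mut_id, chrom=CHROM, pos=int(pos), ref="A", alt="C",
                    depth_ref=depth[0], depth_alt=depth[1], in_dbsnp=in_dbsnp,
                    in_normal=in_normal, blacklisted=blacklisted, kind=kind,
                )
            )
            if in_dbsnp:
                bundle.dbsnp_positions.add(int(pos))
            return mut_id

        def add_reads(mut_id, pos, delta):
            cpgs = [int(pos) + (j - 4) * 90 - (25 if j >= 4 else 0) for j in range(8)]
            mu_r = np.clip(DENOVO_BASELINE + delta / 2, 0.02, 0.98)
            mu_a = np.clip(DENOVO_BASELINE - delta / 2, 0.02, 0.98)
            for allele, mu in ((REF, mu_r), (ALT, mu_a)):
                n = max(int(rng.poisson(cfg.coverage_mean)), 8)
                meth = rng.random((n, len(cpgs))) < mu
                for r in range(n):
                    reads.append(
                        AlleleRead(
                            read_id=f"{mut_id}:{allele}:{r}", mate=1, strand="+",
                            allele=allele, snp_id=mut_id,
                            cpg_calls=[(p, int(m)) for p, m in zip(cpgs, meth[r])],
                            ch_total=20, ch_unconverted=0,
                            start=cpgs[0] - 10, length=cpgs[-1] - cpgs[0] + 20,
                        )
                    )

        def add_window(mut_id, pwm=None, disrupt=True):
            wrng = rng_for(cfg.seed, "somwin", mut_id)
            seq = list(_random_seq(wrng, WINDOW))
            center = WINDOW // 2
            if pwm is not None:
                j = len(pwm) // 2
                start = center - j
                seq[start : start + len(pwm)] = list(pwm.consensus)
                col = pwm.matrix[j]
                best = int(np.argmax(col))
                worst = int(np.argmin(col))
                if disrupt:  # REF (germline) intact, mutation destroys
                    ref_b, alt_b = best, worst
                else:  # mutation creates a de novo motif
                    ref_b, alt_b = worst, best
                seq[center] = BASES[ref_b]
                seq_ref = "".join(seq)
                seq[center] = BASES[alt_b]
                seq_alt = "".join(seq)
            else:
                seq[center] = "A"
                seq_ref = "".join(seq)
                seq[center] = "C"
                seq_alt = "".join(seq)
            bundle.somatic_windows[mut_id] = SnpWindow(mut_id, seq_ref, seq_alt, center)

        region = base + si * 400_000
        # germline dbSNP hets shared with the matched normal
        for g in range(4):
            add_variant(region + g * 3000, "germline", in_dbsnp=True, in_normal=True)
        # non-dbSNP variants present in the matched normal
        for g in range(2):
            add_variant(region + 20_000 + g * 3000, "shared", in_normal=True)
        # under-covered candidate
        add_variant(region + 30_000, "lowdepth", depth=(9, 22))
        # blacklisted candidate
        add_variant(region + 33_000, "blacklisted", blacklisted=True)
        bundle.blacklist.append((CHROM, region + 33_000 - 50, region + 33_000 + 50))
        # mutations next to known ASM index SNPs (uncover germline ASM)
        for g in range(2):
            locus = asm_loci[(si + g) % len(asm_loci)]
            mid = add_variant(locus.pos + 600, "near_known")
            add_reads(mid, locus.pos + 600, DENOVO_DELTA)
            add_window(mid)
            bundle.somatic_truth[(sample.sample_id, mid)] = "near_known"
        # clean somatic mutations: a planted fraction with de novo ASM
        n_clean, n_denovo = 20, 5
        for g in range(n_clean):
            pos = region + 60_000 + g * 4000
            mid = add_variant(pos, "clean")
            if g < n_denovo:
                add_reads(mid, pos, DENOVO_DELTA)
                pwm = pwms[g % len(pwms)]
                add_window(mid, pwm=pwm, disrupt=(g % 2 == 0))
                bundle.somatic_truth[(sample.sample_id, mid)] = "denovo"
            else:
                add_reads(mid, pos, 0.0)
                add_window(mid, pwm=None)
                bundle.somatic_truth[(sample.sample_id, mid)] = "nonasm"
        bundle.somatic_variants[sample.sample_id] = variants
        bundle.somatic_reads[sample.sample_id] = reads


def simulate_annotations_and_panel(cohort: Cohort, truth: TruthTable, pwms,
                                   config: SimConfig | None = None) -> AnnotationBundle:
    """Generate every annotation fixture with ground truth wired to
    ``truth``: DNase pseudo-cell-type tracks, chromatin-state tracks,
    blacklist, imprinted TSS list, phased panel with block LD, GWAS
    catalog, and paired somatic/germline variants with reads."""
    cfg = config or cohort.config
    rng = rng_for(cfg.seed, "annot")
    bundle = AnnotationBundle()

    for locus in cohort.loci:
        lid = locus.snp_id
        if truth.desert[lid]:
            n_tracks = int(rng.integers(0, 2))  # 0 or 1 DNase track
        else:
            n_tracks = int(rng.integers(3, min(20, cfg.n_dnase_tracks)))
        tracks = rng.choice(cfg.n_dnase_tracks, size=n_tracks, replace=False)
        for t in tracks:
            bundle.dnase.append(
                (locus.chrom, locus.pos - 200, locus.pos + 200, f"dnase_{t:03d}")
            )
        state = truth.chrom_state[lid]
        bundle.states.append(
            (locus.chrom, locus.pos - 400, locus.pos + 400, state, "cell_1")
        )
        # a second pseudo-cell-line: deserts stay quiescent everywhere
        second = "quiescent" if truth.desert[lid] else state
        bundle.states.append(
            (locus.chrom, locus.pos - 300, locus.pos + 300, second, "cell_2")
        )
        if locus.blacklisted:
            bundle.blacklist.append((locus.chrom, locus.pos - 100, locus.pos + 100))

    imprinted = [l for l in cohort.loci if truth.locus_class[l.snp_id] == "imprinted"]
    for i, locus in enumerate(imprinted):
        if i % 2 == 0:  # half the imprinted loci are in the known list
            bundle.imprinted_tss.append(
                (locus.chrom, locus.pos + 2000, f"IMP_{locus.snp_id}")
            )

    # GWAS: link every other genotype-ASM locus; one coinciding peak;
    # one sub-threshold row that the catalog filter must drop
    geno = [l.snp_id for l in cohort.loci if truth.locus_class[l.snp_id] == "genotype_ASM"]
    gwas_linked = set(geno[::2])
    snp_col = _simulate_panel(cohort, cfg, bundle, gwas_linked, rng)
    rows = []
    for i, lid in enumerate(sorted(gwas_linked)):
        rows.append(
            dict(
                snp_id=f"gw_{lid}", chrom=CHROM,
                pos=cohort.locus(lid).pos + 1500,
                trait=GWAS_TRAITS[i % len(GWAS_TRAITS)], p=1e-9,
            )
        )
    if geno[1::2]:
        coincide = cohort.locus(geno[1])
        rows.append(
            dict(snp_id="gw_coincide", chrom=CHROM, pos=coincide.pos,
                 trait=GWAS_TRAITS[0], p=1e-10)
        )
    rows.append(
        dict(snp_id="gw_subthreshold", chrom=CHROM,
             pos=cohort.loci[0].pos + 3000, trait="weak_trait", p=1e-5)
    )
    bundle.gwas = pd.DataFrame(rows)

    _simulate_somatic(cohort, truth, cfg, bundle, pwms)
    return bundle
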