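"""Cohort structure, locus classes, and per-allele methylation ground truth.

The simulated genome is a single contig ("chrS" by default) with index-SNP
loci placed on a regular grid.  Each locus belongs to exactly one class:

``none``
    no allelic asymmetry; baseline methylation drawn from a bimodal
    (low/high) genome-wide landscape.
``genotype_ASM``
    heterozygotes show a fixed-direction methylation difference whose
    magnitude is driven by the planted PWM score difference of a motif
    disrupted by the ALT allele (higher-affinity REF allele hypomethylated).
``imprinted``
    every individual shows ASM; the hypermethylated parental allele is REF
    or ALT with probability 1/2 independently per individual.
``switching``
    genotype-dependent ASM whose direction flips in a minority of
    individuals (haplotype-effect emulation).
``cancer_LOM`` / ``cancer_GOM``
    biallelically high (resp. low) methylation in normal samples; cancer
    heterozygotes lose (resp. gain) methylation on one allele, the affected
    allele chosen at random per individual.  GOM loci carry a poised-promoter
    chromatin state.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..config import SimConfig, rng_for
from ..types import ConfigurationError

CHROM = "chrS"
LOCUS_CLASSES = (
    "none",
    "genotype_ASM",
    "imprinted",
    "cancer_LOM",
    "cancer_GOM",
    "switching",
)

NORMAL_CELL_TYPES = ("Tcell", "Bcell", "glia", "liver")
CANCER_CELL_TYPES = ("myeloma", "lymphoma", "GBM")
MATCHED_NORMAL = {"myeloma": "Bcell", "lymphoma": "Bcell", "GBM": "glia"}

LOM_LEVEL = 0.20  # methylation of the allele that loses methylation in cancer
GOM_LEVEL = 0.75  # methylation of the allele that gains methylation in cancer


@dataclass
class Sample:
    sample_id: str
    individual_id: str
    cancer: bool
    cell_type: str
    matched_normal: str | None = None  # sample_id of paired normal (cancer only)


@dataclass
class Locus:
    snp_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float
    locus_class: str
    cpg_positions: list
    coverage_multiplier: float = 1.0
    blacklisted: bool = False


@dataclass
class TruthTable:
    """Ground truth: one entry per simulated locus."""

    locus_class: dict = field(default_factory=dict)  # snp_id -> class
    delta: dict = field(default_factory=dict)  # snp_id -> planted |delta|
    motif_id: dict = field(default_factory=dict)  # snp_id -> causal motif or None
    planted_dpwm: dict = field(default_factory=dict)  # snp_id -> score diff (bits)
    chrom_state: dict = field(default_factory=dict)  # snp_id -> state label
    desert: dict = field(default_factory=dict)  # snp_id -> bool
    # snp_id -> individual_id -> hypermethylated allele ("REF"|"ALT")
    hyper_allele: dict = field(default_factory=dict)
    # snp_id -> sample_id -> (mu_ref, mu_alt)
    allele_means: dict = field(default_factory=dict)
    baseline: dict = field(default_factory=dict)  # snp_id -> baseline methylation

    def to_json_dict(self) -> dict:
        return {
            "locus_class": self.locus_class,
            "delta": self.delta,
            "motif_id": self.motif_id,
            "planted_dpwm": self.planted_dpwm,
            "chrom_state": self.chrom_state,
            "desert": self.desert,
            "hyper_allele": self.hyper_allele,
            "allele_means": {
                s: {k: list(v) for k, v in d.items()}
                for s, d in self.allele_means.items()
            },
            "baseline": self.baseline,
        }

    @classmethod
    def from_json_dict(cls, data: dict) -> "TruthTable":
        tt = cls(**{k: data[k] for k in data if k != "allele_means"})
        tt.allele_means = {
            s: {k: tuple(v) for k, v in d.items()}
            for s, d in data["allele_means"].items()
        }
        return tt


@dataclass
class Cohort:
    config: SimConfig
    samples: list  # [Sample]
    loci: list  # [Locus]
    genotypes: dict  # snp_id -> sample_id -> ALT dosage 0|1|2

    @property
    def sample_ids(self):
        return [s.sample_id for s in self.samples]

    def sample(self, sample_id: str) -> Sample:
        return next(s for s in self.samples if s.sample_id == sample_id)

    def locus(self, snp_id: str) -> Locus:
        return next(l for l in self.loci if l.snp_id == snp_id)

    def het_samples(self, snp_id: str):
        return [s for s, g in self.genotypes[snp_id].items() if g == 1]


def _class_allocation(cfg: SimConfig, rng: np.random.Generator):
    """Deterministic class counts (rounded fractions), interleaved placement."""
    n = cfg.n_loci
    n_gen = round(cfg.genotype_asm_fraction * n)
    n_imp = round(cfg.imprinted_fraction * n)
    n_swi = round(cfg.switching_fraction * n)
    n_can = round(cfg.cancer_only_fraction * n)
    n_gom = round(cfg.gom_share_of_cancer_only * n_can)
    n_lom = n_can - n_gom
    if n_gen + n_imp + n_swi + n_can > n:
        raise ConfigurationError("class fractions allocate more loci than n_loci")
    labels = (
        ["genotype_ASM"] * n_gen
        + ["imprinted"] * n_imp
        + ["switching"] * n_swi
        + ["cancer_LOM"] * n_lom
        + ["cancer_GOM"] * n_gom
    )
    labels += ["none"] * (n - len(labels))
    order = rng.permutation(n)
    out = [""] * n
    for slot, lab in zip(order, labels):
        out[slot] = lab
    return out


def _draw_baseline(locus_class: str, cfg: SimConfig, rng: np.random.Generator):
    lo, hi = cfg.global_meth_modes
    if locus_class == "cancer_LOM":
        return float(np.clip(rng.beta(*hi), 0.78, 0.95))
    if locus_class == "cancer_GOM":
        return float(np.clip(rng.beta(*lo), 0.03, 0.20))
    if locus_class in ("genotype_ASM", "imprinted", "switching"):
        # mid-range so that +/- delta/2 stays inside [0, 1]
        return float(rng.uniform(0.35, 0.65))
    if rng.random() < cfg.high_mode_weight:
        return float(rng.beta(*hi))
    return float(rng.beta(*lo))


def set_allele_means(cohort: Cohort, truth: TruthTable) -> None:
    """(Re)compute per-sample per-allele methylation means from planted
    deltas, directions, and baselines.  Called once by :func:`simulate_cohort`
    and again after the motif landscape rescales genotype-ASM deltas."""
    cfg = cohort.config
    shift = cfg.cancer_hypomethylation_shift
    for locus in cohort.loci:
        lid = locus.snp_id
        cls = truth.locus_class[lid]
        base = truth.baseline[lid]
        d = truth.delta[lid]
        per_sample = {}
        for s in cohort.samples:
            g = cohort.genotypes[lid][s.sample_id]
            # global cancer hypomethylation of the highly methylated fraction
            b = base
            if s.cancer and cls in ("none", "genotype_ASM", "switching") and base > 0.5:
                b = max(base - shift, 0.10)
            mu_ref = mu_alt = b
            het = g == 1
            if cls == "genotype_ASM" and het:
                # REF carries the intact (higher-affinity) motif -> hypomethylated
                mu_ref, mu_alt = b - d / 2.0, b + d / 2.0
            elif cls == "switching" and het:
                hyper = truth.hyper_allele[lid][s.individual_id]
                if hyper == "REF":
                    mu_ref, mu_alt = b + d / 2.0, b - d / 2.0
                else:
                    mu_ref, mu_alt = b - d / 2.0, b + d / 2.0
            elif cls == "imprinted":
                hyper = truth.hyper_allele[lid][s.individual_id]
                if hyper == "REF":
                    mu_ref, mu_alt = b + d / 2.0, b - d / 2.0
                else:
                    mu_ref, mu_alt = b - d / 2.0, b + d / 2.0
            elif cls == "cancer_LOM" and s.cancer and het:
                low = truth.hyper_allele[lid][s.individual_id]
                # the *hypo*methylated allele is recorded as the non-hyper one
                if low == "REF":
                    mu_ref, mu_alt = base, LOM_LEVEL
                else:
                    mu_ref, mu_alt = LOM_LEVEL, base
            elif cls == "cancer_GOM" and s.cancer and het:
                hyper = truth.hyper_allele[lid][s.individual_id]
                if hyper == "REF":
                    mu_ref, mu_alt = GOM_LEVEL, base
                else:
                    mu_ref, mu_alt = base, GOM_LEVEL
            per_sample[s.sample_id] = (
                float(np.clip(mu_ref, 0.02, 0.98)),
                float(np.clip(mu_alt, 0.02, 0.98)),
            )
        truth.allele_means[lid] = per_sample


def simulate_cohort(config: SimConfig):
    """Build samples, loci, HWE genotypes, and the ground-truth table.

    Returns ``(cohort, truth)``.  Deterministic under ``config.seed``.
    """
    if not isinstance(config, SimConfig):
        raise ConfigurationError("config must be a SimConfig")
    rng = rng_for(config.seed, "cohort")

    samples = []
    for i in range(config.n_normal_samples):
        ct = NORMAL_CELL_TYPES[i % len(NORMAL_CELL_TYPES)]
        samples.append(Sample(f"N{i+1:03d}", f"ind_N{i+1:03d}", False, ct))
    normals_by_type: dict = {}
    for s in samples:
        normals_by_type.setdefault(s.cell_type, []).append(s.sample_id)
    for i in range(config.n_cancer_samples):
        ct = CANCER_CELL_TYPES[i % len(CANCER_CELL_TYPES)]
        matched_pool = normals_by_type.get(MATCHED_NORMAL[ct], [])
        matched = matched_pool[i % len(matched_pool)] if matched_pool else None
        samples.append(Sample(f"C{i+1:03d}", f"ind_C{i+1:03d}", True, ct, matched))

    classes = _class_allocation(config, rng)
    truth = TruthTable()
    loci = []
    # a couple of explicitly planted filter targets among the null loci
    none_idx = [i for i, c in enumerate(classes) if c == "none"]
    overcov_idx = set(none_idx[:1])
    blacklist_idx = set(none_idx[1:3])
    snp_bases = [("A", "C"), ("T", "G"), ("A", "T"), ("C", "G")]
    for i, cls in enumerate(classes):
        pos = 5000 + i * config.locus_spacing
        ref, alt = snp_bases[i % len(snp_bases)]
        half = config.n_cpg_per_locus // 2
        cpgs = [
            pos + (k - half) * config.cpg_spacing - (25 if k >= half else 0)
            for k in range(config.n_cpg_per_locus)
        ]
        locus = Locus(
            snp_id=f"rsS{i:05d}",
            chrom=CHROM,
            pos=pos,
            ref=ref,
            alt=alt,
            maf=config.maf,
            locus_class=cls,
            cpg_positions=cpgs,
            coverage_multiplier=15.0 if i in overcov_idx else 1.0,
            blacklisted=i in blacklist_idx,
        )
        loci.append(locus)
        truth.locus_class[locus.snp_id] = cls
        truth.baseline[locus.snp_id] = _draw_baseline(cls, config, rng)
        truth.delta[locus.snp_id] = config.asm_effect if cls != "none" else 0.0
        truth.motif_id[locus.snp_id] = None
        truth.planted_dpwm[locus.snp_id] = 0.0

    # chromatin state and desert flags
    state_cycle = ("active_promoter", "strong_enhancer", "quiescent", "weak_txn")
    n_desert = round(config.desert_fraction * config.n_loci)
    desert_candidates = [
        l.snp_id for l in loci if l.locus_class in ("none", "genotype_ASM")
    ]
    desert_ids = set(desert_candidates[:n_desert])
    j = 0
    for locus in loci:
        lid = locus.snp_id
        if locus.locus_class == "cancer_GOM":
            truth.chrom_state[lid] = "poised_promoter"
            truth.desert[lid] = False
        elif lid in desert_ids:
            truth.chrom_state[lid] = "quiescent"
            truth.desert[lid] = True
        else:
            truth.chrom_state[lid] = state_cycle[j % len(state_cycle)]
            truth.desert[lid] = False
            j += 1

    # HWE genotypes and per-individual allele directions
    genotypes: dict = {}
    for locus in loci:
        p = locus.maf
        g_rng = rng_for(config.seed, "geno", locus.snp_id)
        probs = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
        gts = g_rng.choice(3, size=len(samples), p=probs)
        genotypes[locus.snp_id] = {
            s.sample_id: int(g) for s, g in zip(samples, gts)
        }
        cls = locus.locus_class
        dir_rng = rng_for(config.seed, "dir", locus.snp_id)
        hyp: dict = {}
        for s in samples:
            if cls == "imprinted" or cls in ("cancer_LOM", "cancer_GOM"):
                hyp[s.individual_id] = "REF" if dir_rng.random() < 0.5 else "ALT"
            elif cls == "switching":
                hyp[s.individual_id] = (
                    "ALT" if dir_rng.random() < config.switch_minority_rate else "REF"
                )
        if hyp:
            truth.hyper_allele[locus.snp_id] = hyp

    cohort = Cohort(config=config, samples=samples, loci=loci, genotypes=genotypes)
    set_allele_means(cohort, truth)
    return cohort, truth
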