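"""Configuration objects for the simulator and the pipeline driver.

Every threshold of the analysis stages is a named key with its published
default; unknown keys in a config file are rejected.
"""
from __future__ import annotations

import dataclasses
import tomllib
import zlib
from dataclasses import dataclass, field

import numpy as np

from .types import ConfigurationError


def rng_for(seed: int, *keys) -> np.random.Generator:
    """Deterministic child generator for (seed, keys).

    Strings are hashed with crc32 so the stream depends only on the logical
    key, never on call order.  Keeps all entropy words below 2**32.
    """
    words = [int(seed) % (2**31)]
    for k in keys:
        if isinstance(k, str):
            words.append(zlib.crc32(k.encode()) % (2**32))
        else:
            words.append(int(k) % (2**32))
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(words)))


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort.

    The defaults describe a desk-scale cohort emulating the structure of a
    multi-tissue normal + cancer methyl-seq series: mostly-null loci, a
    genotype-dependent ASM class whose effect size tracks planted PWM score
    differences, imprinted loci with 50:50 parental assignment, switching
    loci, and cancer-only LOM/GOM loci.
    """

    n_normal_samples: int = 28
    n_cancer_samples: int = 8
    n_loci: int = 120
    coverage_mean: float = 20.0  # reads per allele
    asm_effect: float = 0.4  # fractional methylation difference delta
    # (a, b) beta parameters of the low and high genome-wide methylation modes
    global_meth_modes: tuple = ((2.0, 12.0), (12.0, 2.0))
    high_mode_weight: float = 0.65
    cancer_hypomethylation_shift: float = 0.3
    genotype_asm_fraction: float = 0.25
    imprinted_fraction: float = 0.10
    switching_fraction: float = 0.05
    cancer_only_fraction: float = 0.20
    gom_share_of_cancer_only: float = 0.3
    switch_minority_rate: float = 0.3  # minority-direction rate at switching loci
    maf: float = 0.5
    n_cpg_per_locus: int = 8
    cpg_spacing: int = 90
    # wide spacing keeps each locus outside its neighbours' 150 kb
    # imprinted-TSS windows and LD neighbourhoods
    locus_spacing: int = 80_000
    conversion_failure_rate: float = 0.01
    ambiguous_rate: float = 0.02
    desert_fraction: float = 0.15
    n_dnase_tracks: int = 122
    n_panel_individuals: int = 120
    panel_founders_per_block: int = 4
    panel_block_snps: int = 5
    seed: int = 0

    def __post_init__(self):
        fracs = {
            "genotype_asm_fraction": self.genotype_asm_fraction,
            "imprinted_fraction": self.imprinted_fraction,
            "switching_fraction": self.switching_fraction,
            "cancer_only_fraction": self.cancer_only_fraction,
        }
        for name, f in fracs.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"{name}={f} outside [0,1]")
        if sum(fracs.values()) > 1.0 + 1e-9:
            raise ConfigurationError("locus-class fractions sum to > 1")
        if self.coverage_mean <= 0:
            raise ConfigurationError("coverage_mean must be > 0")
        if not 0.0 <= self.asm_effect <= 1.0:
            raise ConfigurationError("asm_effect must be in [0,1]")
        if not 0.0 <= self.maf <= 0.5:
            raise ConfigurationError("maf must be in [0, 0.5]")
        if len(self.global_meth_modes) != 2:
            raise ConfigurationError("global_meth_modes must be (low, high) pairs")


@dataclass
class PipelineConfig:
    """Thresholds for every analysis stage, defaulting to published values."""

    # extraction
    window_bp: int = 2000  # extraction window centered on the index SNP
    min_reads_per_allele: int = 5  # SNPs with fewer are filtered out
    max_total_coverage: int = 200
    hwe_fdr: float = 0.05
    secondary_maf_max: float = 0.05
    common_snp_maf: float = 0.05  # CpGs destroyed by SNPs above this are dropped
    max_ch_unconverted_frac: float = 0.10
    protocol: str = "SureSelect"
    wgbs_mode: bool = False  # if True, C/T and G/A SNPs kept with strand filtering
    # DMR calling
    cpg_fisher_alpha: float = 0.05
    min_asm_cpgs: int = 3
    min_consecutive_asm: int = 2
    min_eligible_cpgs: int = 3
    per_cpg_min_depth: int = 5  # eligibility requires more than this per allele
    min_mean_delta: float = 0.20  # strict >
    dmr_fdr: float = 0.05
    merge_gap_bp: int = 250  # strict <
    wilcoxon_kind: str = "signed_rank"  # or "rank_sum"
    # catalog
    min_recurrent_samples: int = 2
    switching_min_het_samples: int = 2  # scored only when het in more than this
    imprint_window_bp: int = 150_000
    imprint_min_individuals: int = 10  # candidate requires ASM in more than this
    imprint_min_switching: float = 0.20
    # motifs
    pwm_pseudocount: float = 0.25
    disruption_q: float = 0.05
    binding_p: float = 0.005
    enrichment_or: float = 2.0
    enrichment_q: float = 0.05
    min_disrupted_occurrences: int = 10  # strict > for correlation analysis
    background_cap: int = 40_000
    background_ratio: int = 3
    correlation_fdr: float = 0.05
    correlation_r2: float = 0.4
    chip_min_occurrences: int = 10
    chip_min_fold: float = 10.0
    # class models
    meth_low: float = 0.3
    meth_high: float = 0.7
    min_model_loci: int = 10
    interaction_min_total: int = 10
    interaction_min_per_class: int = 3
    # annotation
    small_window_bp: int = 1000
    large_window_bp: int = 150_000
    desert_max_dnase: int = 1
    strong_states: tuple = (
        "active_promoter",
        "strong_enhancer",
        "poised_promoter",
        "poised_enhancer",
        "insulator",
    )
    asb_min_reads: int = 10
    asb_fdr: float = 0.05
    # LD / GWAS
    gwas_p_max: float = 1e-6
    ld_max_dist: int = 200_000
    r2_high: float = 0.8
    stringent_ci: tuple = (0.70, 0.98)
    lenient_ci: tuple = (0.60, 0.84)
    recomb_ci_high: float = 0.90
    stringent_informative_frac: float = 0.95
    lenient_informative_frac: float = 0.55
    lenient_max_block_bp: int = 200_000
    # somatic
    somatic_min_depth_per_allele: int = 10
    denovo_exclusion_bp: int = 1000
    denovo_or: float = 2.0
    denovo_p: float = 0.05
    # bootstrap validation
    bootstrap_n: int = 1000
    bootstrap_reads: int = 50
    bootstrap_min_depth: int = 100
    seed: int = 0

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("global_meth_modes", "strong_states", "stringent_ci", "lenient_ci"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in data[key]
                )
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
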