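"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open internally; VCF is 1-based and BED 0-based
half-open at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

PROTOCOLS = ("SureSelect", "Nextera", "TruSeq", "ACCEL")

#: allele labels for allele-resolved reads
REF, ALT, AMBIG = "REF", "ALT", "AMBIG"


@dataclass
class AlleleRead:
    """One sequencing read (one mate of a pair) tagged with its allele call
    at an index SNP and its per-CpG methylation calls.

    ``cpg_calls`` is a list of ``(position, meth)`` with ``meth`` in {0, 1},
    positions strictly increasing.  ``start``/``length`` give the genomic span
    of the read, needed to apply protocol-specific positional masks.
    """

    read_id: str
    mate: int  # 1 | 2
    strand: str  # '+' | '-'
    allele: str  # REF | ALT | AMBIG
    snp_id: str
    cpg_calls: list  # [(pos, meth)]
    ch_total: int = 0
    ch_unconverted: int = 0
    protocol: str = "SureSelect"
    start: int = 0
    length: int = 0

    def __post_init__(self):
        if self.ch_unconverted > self.ch_total:
            raise ValueError("ch_unconverted exceeds ch_total")
        pos = [p for p, _ in self.cpg_calls]
        if pos != sorted(set(pos)):
            raise ValueError("CpG positions must be strictly increasing")


@dataclass
class IndexSnp:
    """A heterozygous, biallelic index SNP used to split reads by allele."""

    snp_id: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    genotypes: dict = field(default_factory=dict)  # sample_id -> 0|1|2 (ALT dosage)
    maf: float = 0.5
    secondary_maf: float = 0.0

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"{self.snp_id}: ref == alt")

    @property
    def snp_class(self) -> str:
        pair = {self.ref.upper(), self.alt.upper()}
        if pair == {"C", "T"}:
            return "C/T"
        if pair == {"G", "A"}:
            return "G/A"
        return "other"


@dataclass
class CpGAlleleCounts:
    """Methylated/unmethylated read counts per allele at one CpG."""

    snp_id: str
    cpg_pos: int
    m_ref: int
    u_ref: int
    m_alt: int
    u_alt: int
    destroyed_by_common_snp: bool = False

    def __post_init__(self):
        if min(self.m_ref, self.u_ref, self.m_alt, self.u_alt) < 0:
            raise ValueError("negative count")

    @property
    def depth_ref(self) -> int:
        return self.m_ref + self.u_ref

    @property
    def depth_alt(self) -> int:
        return self.m_alt + self.u_alt

    @property
    def frac_ref(self) -> float:
        return self.m_ref / self.depth_ref if self.depth_ref else float("nan")

    @property
    def frac_alt(self) -> float:
        return self.m_alt / self.depth_alt if self.depth_alt else float("nan")


@dataclass
class CpgAsmResult:
    """Per-CpG allelic asymmetry test result."""

    snp_id: str
    cpg_pos: int
    fisher_p: float
    delta: float  # frac_ref - frac_alt
    eligible: bool
    frac_ref: float = float("nan")
    frac_alt: float = float("nan")


@dataclass
class AsmDmr:
    """A called ASM region for one sample, tagged by its index SNP."""

    sample_id: str
    snp_id: str
    span: tuple  # (first_asm_cpg_pos, last_asm_cpg_pos)
    n_cpg_covered: int
    n_asm_cpg: int
    max_consecutive_asm: int
    mean_delta: float
    wilcoxon_p: float
    fdr_q: float = float("nan")
    avg_allele_coverage: float = float("nan")

    @property
    def direction(self) -> str:
        return "REF_hyper" if self.mean_delta > 0 else "ALT_hyper"


@dataclass
class CatalogEntry:
    """Cross-sample aggregation of ASM evidence at one index SNP."""

    snp_id: str
    n_informative_samples: int
    n_asm_samples: int
    asm_sample_ids: dict = field(default_factory=dict)  # sample_id -> direction
    confidence_score: float = float("nan")
    strength_score: float = float("nan")
    confidence_rank: int = 0
    strength_rank: int = 0
    overall_rank: int = 0
    switching_fraction: Optional[float] = None
    switch_flag: Optional[bool] = None
    asm_class: Optional[str] = None  # normal_ASM | cancer_only_ASM
    imprint_flag: str = "none"  # known | candidate | none


@dataclass
class SampleSummary:
    sample_id: str
    cancer: bool
    global_mean_methylation: float
    asm_frequency: float


@dataclass
class MotifOccurrence:
    """One PWM occurrence overlapping an index SNP, scored per allele."""

    snp_id: str
    motif_id: str
    strand: str
    snp_offset: int
    score_ref: float
    score_alt: float
    p_ref: float
    p_alt: float
    p_diff: float = float("nan")
    q_diff: float = float("nan")
    contains_cpg: bool = False
    mean_delta_meth: float = float("nan")

    @property
    def score_diff(self) -> float:
        return self.score_ref - self.score_alt


@dataclass
class SomaticMutation:
    chrom: str
    pos: int
    ref: str
    alt: str
    depth_ref: int
    depth_alt: int
    in_dbsnp: bool = False
    in_matched_normal: bool = False
    dist_to_known_asm: Optional[int] = None
    sample_id: str = ""

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        if min(self.depth_ref, self.depth_alt) < 0:
            raise ValueError("negative depth")


@dataclass
class LdStats:
    snp_a: str
    snp_b: str
    d: float
    d_prime: float
    r2: float
    ci_low: float
    ci_high: float


@dataclass
class HaploBlock:
    chrom: str
    start: int
    end: int
    snp_ids: list
    mode: str  # stringent | lenient


class ConfigurationError(ValueError):
    """Invalid configuration or unknown vocabulary value."""


class FormatError(ValueError):
    """Malformed input file content."""
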