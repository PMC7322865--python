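"""Window-based annotation of index SNPs: chromatin states and DNase
peaks in a small (1 kb) window, chromatin-desert calling, logistic
feature enrichment with cancer-status stratification and differential
(interaction) enrichment, and allele-specific binding (ASB) calls with
ASM-ASB concordance.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .motifs import _logit_or
from .types import FormatError

DEFAULT_STRONG_STATES = (
    "active_promoter",
    "strong_enhancer",
    "poised_promoter",
    "poised_enhancer",
    "insulator",
)


@dataclass
class SnpAnnotation:
    snp_id: str
    states: set = field(default_factory=set)  # state labels in the small window
    n_dnase_tracks_with_peak: int = 0
    desert: bool = False
    eqtl: bool = False
    asb: bool = False
    gwas_traits: list = field(default_factory=list)


def intersect_annotations(snp_positions: dict, dnase, states,
                          small_window_bp: int = 1000):
    """Per-SNP annotation flags from BED-style interval lists.

    ``snp_positions``: snp_id -> (chrom, pos).  ``dnase`` rows are
    ``(chrom, start, end, track)``; ``states`` rows are
    ``(chrom, start, end, state, track)``.  All states observed in any
    track within the half-open small window are flagged.
    """
    for name, rows, n in (("dnase", dnase, 4), ("states", states, 5)):
        for i, iv in enumerate(rows):
            if len(iv) < n:
                raise FormatError(f"{name} interval {i}: expected {n} fields")
    dnase_by_chrom: dict = {}
    for chrom, start, end, track in dnase:
        tree = dnase_by_chrom.setdefault(chrom, IntervalTree())
        if end > start:
            tree[start:end] = track
    state_by_chrom: dict = {}
    for chrom, start, end, state, track in states:
        tree = state_by_chrom.setdefault(chrom, IntervalTree())
        if end > start:
            tree[start:end] = (state, track)
    half = small_window_bp // 2
    out = {}
    for snp_id, (chrom, pos) in snp_positions.items():
        lo, hi = pos - half, pos + half
        tracks = {
            iv.data for iv in dnase_by_chrom.get(chrom, IntervalTree()).overlap(lo, hi)
        }
        labels = {
            iv.data[0]
            for iv in state_by_chrom.get(chrom, IntervalTree()).overlap(lo, hi)
        }
        out[snp_id] = SnpAnnotation(
            snp_id=snp_id, states=labels, n_dnase_tracks_with_peak=len(tracks)
        )
    return out


def call_desert(annotation: SnpAnnotation, max_dnase: int = 1,
                strong_states=DEFAULT_STRONG_STATES) -> bool:
    """A chromatin desert has at most ``max_dnase`` DNase-positive tracks
    and no strong promoter/enhancer, poised, or insulator state in any
    track."""
    if annotation.n_dnase_tracks_with_peak > max_dnase:
        return False
    return not (annotation.states & set(strong_states))


def annotate_deserts(annotations: dict, max_dnase: int = 1,
                     strong_states=DEFAULT_STRONG_STATES):
    for ann in annotations.values():
        ann.desert = call_desert(ann, max_dnase, strong_states)
    return annotations


def feature_enrichment(asm_snps, informative_background, feature_flags: dict,
                       strata: dict | None = None):
    """Logistic enrichment of a binary feature among ASM index SNPs
    against the full informative background.

    ``feature_flags``: snp_id -> bool.  With ``strata`` (snp_id -> label)
    the analysis is repeated per stratum.  Returns a DataFrame with
    odds_ratio, p (Fisher fallback under separation), and stratum.
    """
    asm_snps = set(asm_snps)
    background = [s for s in informative_background]
    rows = []
    groups = {"all": background}
    if strata is not None:
        for s in background:
            groups.setdefault(strata.get(s, "all"), []).append(s)
    for label, snps in groups.items():
        y = np.array([s in asm_snps for s in snps], dtype=float)
        x = np.array([bool(feature_flags.get(s, False)) for s in snps], dtype=float)
        if y.sum() == 0 or x.sum() == 0:
            rows.append(dict(stratum=label, odds_ratio=None, p=None,
                             n_asm=int(y.sum()), n=len(snps)))
            continue
        odds, p = _logit_or(y, x)
        rows.append(dict(stratum=label, odds_ratio=odds, p=p,
                         n_asm=int(y.sum()), n=len(snps)))
    return pd.DataFrame(rows)


def differential_enrichment(snp_ids, asm_flags: dict, class_flags: dict,
                            feature_flags: dict):
    """Interaction model: does the feature enrichment differ between the
    cancer and normal ASM classes?

    Logistic model ``feature ~ asm * cancer_class``; the interaction OR
    compares the cancer-class enrichment with the normal-class one.
    """
    snp_ids = list(snp_ids)
    if not snp_ids:
        raise ValueError("no SNPs supplied")
    asm = np.array([bool(asm_flags.get(s, False)) for s in snp_ids], dtype=float)
    cls = np.array([bool(class_flags[s]) for s in snp_ids], dtype=float)
    feat = np.array([bool(feature_flags.get(s, False)) for s in snp_ids], dtype=float)
    if cls.all() or not cls.any():
        raise ValueError("both cancer classes must be represented")
    X = sm.add_constant(np.column_stack([asm, cls, asm * cls]))
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.Logit(feat, X).fit(disp=0)
        return dict(
            interaction_or=float(np.exp(fit.params[3])),
            interaction_p=float(fit.pvalues[3]),
        )
    except Exception:  # separation / non-convergence fallback
        o1, _ = _logit_or(feat[cls == 1], asm[cls == 1])
        o0, _ = _logit_or(feat[cls == 0], asm[cls == 0])
        if o0 in (0.0,) or not np.isfinite(o1) or not np.isfinite(o0):
            return dict(interaction_or=None, interaction_p=None)
        return dict(interaction_or=o1 / o0, interaction_p=None)


def asb_call_and_concordance(chip_counts: dict, wgbs_counts: dict,
                             asm_hypo_allele: dict, min_reads: int = 10,
                             fdr: float = 0.05):
    """Allele-specific binding calls and ASM-ASB direction concordance.

    ``chip_counts``/``wgbs_counts``: key -> (ref_reads, alt_reads) for a
    (TF, snp) pair; ``asm_hypo_allele``: key -> "REF"|"ALT", the
    hypomethylated allele.  Sites with <= ``min_reads`` ChIP reads are
    not assessed.  Per-site Fisher exact test of ChIP vs WGBS allelic
    counts with B-H FDR; concordant = the hypomethylated allele has the
    greater ChIP occupancy; pooled one-sided exact binomial test of the
    concordant fraction against 0.5.
    """
    keys, pvals = [], []
    for key, (cr, ca) in chip_counts.items():
        if cr + ca <= min_reads or key not in wgbs_counts:
            continue
        wr, wa = wgbs_counts[key]
        _, p = stats.fisher_exact([[cr, ca], [wr, wa]])
        keys.append(key)
        pvals.append(p)
    if not keys:
        return pd.DataFrame(), dict(n_asb=0, n_concordant=0, binom_p=None)
    reject, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    rows, n_conc, n_asb = [], 0, 0
    for key, p, q, rej in zip(keys, pvals, qvals, reject):
        cr, ca = chip_counts[key]
        wr, wa = wgbs_counts[key]
        # occupancy bias relative to the WGBS allelic balance
        chip_ref_frac = cr / (cr + ca)
        wgbs_ref_frac = wr / (wr + wa)
        bound = "REF" if chip_ref_frac > wgbs_ref_frac else "ALT"
        concordant = None
        if rej:
            n_asb += 1
            hypo = asm_hypo_allele.get(key)
            if hypo is not None:
                concordant = bound == hypo
                n_conc += bool(concordant)
        rows.append(
            dict(key=key, fisher_p=float(p), q=float(q), asb=bool(rej),
                 bound_allele=bound, concordant=concordant)
        )
    binom_p = None
    if n_asb:
        binom_p = float(
            stats.binomtest(n_conc, n_asb, 0.5, alternative="greater").pvalue
        )
    return pd.DataFrame(rows), dict(n_asb=n_asb, n_concordant=n_conc, binom_p=binom_p)
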