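"""Planting of motif-disrupting SNPs in sequence windows.

Each genotype-ASM locus gets a motif consensus embedded in its window with
the SNP sitting on an informative motif column: the REF allele carries the
consensus base, the ALT allele a weaker base.  The planted score difference
is the column log2 probability ratio — independent of the scoring code that
later has to recover it.  The planted methylation effect is proportional to
the planted score difference, so downstream regressions see a negative
(affinity up, methylation down) slope of known magnitude.
"""
from __future__ import annotations

import numpy as np

from ..config import rng_for
from ..pwm import BASES, BASE_INDEX, Pwm, SnpWindow
from ..types import FormatError
from .cohort import Cohort, TruthTable, set_allele_means

WINDOW = 61  # odd, SNP at the center
CENTER_DPWM = 8.0  # bits; the planted delta equals asm_effect at this value

# heterogeneous information profile mimicking real TF count matrices:
# one "critical" contact column (deepest minor-base depletion, where
# disruptive SNPs act), several core columns, and weakly constrained
# flanking columns
CRITICAL_WEIGHTS = np.array([0.970, 0.010, 0.005, 0.0025])
CORE_WEIGHTS = np.array([0.88, 0.06, 0.03, 0.03])
WEAK_WEIGHTS = np.array([0.40, 0.25, 0.20, 0.15])
COUNT_SCALE = 1000  # pseudo count matrix depth


def make_default_pwms(n: int = 12, seed: int = 0, length_range=(16, 20)):
    """Synthetic PWM panel; every other motif carries a CpG in its consensus.

    Each motif has one critical contact column at its center whose
    substitution costs exceed any other single-base change in the motif,
    flanked by moderately constrained core columns and weak columns.
    """
    rng = rng_for(seed, "pwms")
    pwms = []
    for m in range(n):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        counts = np.zeros((L, 4))
        consensus = rng.integers(0, 4, size=L)
        if m % 2 == 0:  # plant a CpG dinucleotide inside the consensus
            cg_at = L // 3
            consensus[cg_at], consensus[cg_at + 1] = BASE_INDEX["C"], BASE_INDEX["G"]
        core = set(range(0, L, 2))
        # bisulfite-confounded partner of each base (C/T and G/A pairs)
        partner = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T
        for i in range(L):
            if i == L // 2:
                weights = CRITICAL_WEIGHTS
                # the deepest minors sit on bases that are safe to plant
                # (not bisulfite-confounded with the consensus base)
                cons = int(consensus[i])
                safe = [b for b in range(4) if b not in (cons, partner[cons])]
                order = [cons, partner[cons], *rng.permutation(safe)]
            elif i in core:
                weights = CORE_WEIGHTS
                order = [consensus[i]] + list(
                    rng.permutation([b for b in range(4) if b != consensus[i]])
                )
            else:
                weights = WEAK_WEIGHTS
                order = [consensus[i]] + list(
                    rng.permutation([b for b in range(4) if b != consensus[i]])
                )
            for rank, b in enumerate(order):
                counts[i, b] = COUNT_SCALE * weights[rank]
        name = "CTCF_like_1" if m == 0 else f"TFM_{m}"
        pwms.append(Pwm.from_counts(name, counts))
    return pwms


def _random_seq(rng, n):
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def simulate_motif_landscape(cohort: Cohort, truth: TruthTable, pwms, seed=None,
                             degenerate_positions: bool = True):
    """Build REF/ALT windows per locus; plant disruptive motifs at
    genotype-ASM loci; rescale their methylation effects to track the
    planted score differences.  Returns ``{snp_id: SnpWindow}``.

    With ``degenerate_positions`` (default) the embedded occurrences draw
    their non-critical positions from the motif model, so occurrences of
    one motif differ at degenerate positions as real binding sites do; the
    best-hit score difference then occasionally undershoots the planted
    critical-column ratio when the weaker allele's best hit shifts to a
    flanking alignment.  With ``False`` the full consensus is embedded and
    the best-hit difference equals the planted ratio exactly.
    """
    for pwm in pwms:
        if len(pwm) < 2:
            raise FormatError(f"{pwm.motif_id}: PWM needs >= 2 columns")
    cfg = cohort.config
    seed = cfg.seed if seed is None else seed
    kappa = cfg.asm_effect / CENTER_DPWM  # methylation change per bit
    windows = {}
    gi = 0
    center = WINDOW // 2
    for locus in cohort.loci:
        rng = rng_for(seed, "window", locus.snp_id)
        lid = locus.snp_id
        cls = truth.locus_class[lid]
        seq = list(_random_seq(rng, WINDOW))
        if cls == "genotype_ASM":
            pwm = pwms[gi % len(pwms)]
            j = len(pwm) // 2  # SNP column inside the motif
            start = center - j
            if degenerate_positions:
                occ_seq = [
                    BASES[rng.choice(4, p=pwm.matrix[i])] for i in range(len(pwm))
                ]
                occ_seq[j] = pwm.consensus[j]
            else:
                occ_seq = list(pwm.consensus)
            seq[start : start + len(pwm)] = occ_seq
            col = pwm.matrix[j]
            ref_b = int(np.argmax(col))
            # plant substitutions to the deepest two admissible minor bases
            # (critical-contact disruptions), cycling for a spread of
            # effects; bisulfite-confounded C/T and G/A pairs are avoided
            ranked = [
                int(b)
                for b in np.argsort(col)[::-1][1:]
                if {BASES[ref_b], BASES[int(b)]} not in ({"C", "T"}, {"G", "A"})
            ]
            deep = ranked[-2:] if len(ranked) >= 2 else ranked
            alt_b = deep[(gi // len(pwms)) % len(deep)]
            seq[center] = BASES[ref_b]
            seq_ref = "".join(seq)
            seq[center] = BASES[alt_b]
            seq_alt = "".join(seq)
            dpwm = float(np.log2(col[ref_b] / col[alt_b]))
            truth.motif_id[lid] = pwm.motif_id
            truth.planted_dpwm[lid] = dpwm
            truth.delta[lid] = float(np.clip(kappa * dpwm, 0.10, 0.80))
            gi += 1
        else:
            # keep the cohort's (non-confounded) allele pair at null loci
            seq[center] = locus.ref
            seq_ref = "".join(seq)
            seq[center] = locus.alt
            seq_alt = "".join(seq)
            ref_b, alt_b = BASE_INDEX[locus.ref], BASE_INDEX[locus.alt]
            truth.motif_id[lid] = None
            truth.planted_dpwm[lid] = 0.0
        # keep VCF alleles consistent with the sequence windows
        locus.ref, locus.alt = BASES[ref_b], BASES[alt_b]
        windows[lid] = SnpWindow(lid, seq_ref, seq_alt, center)
    set_allele_means(cohort, truth)
    return windows
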