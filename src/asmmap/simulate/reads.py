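"""Allele-resolved read simulation.

Each simulated fragment covers every CpG of its locus window, so per-CpG
per-allele methylated counts are Binomial(n_reads, mu) with
n_reads ~ Poisson(coverage_mean) truncated at >= 1.  A configured fraction
of reads carries conversion-failure CH statistics (and saturated
methylation calls), and another fraction is emitted as discordant read
pairs (REF on mate 1, ALT on mate 2) to exercise the ambiguity filter.
"""
from __future__ import annotations

import numpy as np

from ..config import SimConfig, rng_for
from ..types import ALT, REF, AlleleRead, ConfigurationError
from .cohort import Cohort, TruthTable


def simulate_reads(cohort: Cohort, truth: TruthTable, config: SimConfig | None = None,
                   sample_id: str | None = None, protocol: str = "SureSelect"):
    """Generate AlleleRead collections.

    Returns ``{sample_id: [AlleleRead, ...]}`` for heterozygous loci of each
    sample (homozygous loci carry no allele information).  With
    ``sample_id`` given, only that sample is simulated — streams are
    seeded per (seed, sample, locus), so per-sample output is identical
    either way.
    """
    config = config or cohort.config
    if config.coverage_mean <= 0:
        raise ConfigurationError("coverage_mean must be > 0")
    samples = (
        [cohort.sample(sample_id)] if sample_id is not None else cohort.samples
    )
    out = {}
    for sample in samples:
        reads = []
        for locus in cohort.loci:
            if cohort.genotypes[locus.snp_id][sample.sample_id] != 1:
                continue
            rng = rng_for(config.seed, "reads", sample.sample_id, locus.snp_id)
            mu_ref, mu_alt = truth.allele_means[locus.snp_id][sample.sample_id]
            mean_cov = config.coverage_mean * locus.coverage_multiplier
            cpgs = locus.cpg_positions
            start = cpgs[0] - 10
            length = cpgs[-1] - cpgs[0] + 20
            for allele, mu in ((REF, mu_ref), (ALT, mu_alt)):
                n = max(int(rng.poisson(mean_cov)), 1)
                meth = rng.random((n, len(cpgs))) < mu
                bad = rng.random(n) < config.conversion_failure_rate
                ambig = rng.random(n) < config.ambiguous_rate
                for r in range(n):
                    rid = f"{sample.sample_id}:{locus.snp_id}:{allele}:{r}"
                    if bad[r]:
                        calls = [(p, 1) for p in cpgs]
                        ch_tot, ch_unc = 20, 5  # 25% unconverted CH
                    else:
                        calls = [(p, int(m)) for p, m in zip(cpgs, meth[r])]
                        ch_tot, ch_unc = 20, 0
                    if ambig[r]:
                        # discordant pair: REF call on mate 1, ALT on mate 2
                        half = len(calls) // 2
                        for mate, al, cc in (
                            (1, REF, calls[:half]),
                            (2, ALT, calls[half:]),
                        ):
                            reads.append(
                                AlleleRead(
                                    read_id=rid, mate=mate, strand="+", allele=al,
                                    snp_id=locus.snp_id, cpg_calls=cc,
                                    ch_total=ch_tot, ch_unconverted=ch_unc,
                                    protocol=protocol, start=start, length=length,
                                )
                            )
                    else:
                        reads.append(
                            AlleleRead(
                                read_id=rid, mate=1, strand="+", allele=allele,
                                snp_id=locus.snp_id, cpg_calls=calls,
                                ch_total=ch_tot, ch_unconverted=ch_unc,
                                protocol=protocol, start=start, length=length,
                            )
                        )
        out[sample.sample_id] = reads
    return out
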