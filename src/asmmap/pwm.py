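"""Position weight matrices: container, JASPAR I/O, and exact score nulls.

Scores are log2 likelihood ratios against a zero-order background.  The
null distribution of a single-offset score is computed exactly by
column-wise convolution on a discretized grid (1e-3 bins); the null of the
best score over offsets and strands uses a Sidak combination of the
per-offset tail.  The REF-ALT score difference is tested against a paired
empirical null (seeded, cached per motif): background windows sharing
their flanks between the two alleles, best hit per allele over all
SNP-covering alignments — pairing matters because the best hit can shift
alignment to dodge an unfavourable SNP base.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as bio_motifs

from .types import FormatError

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

GRID = 1e-3  # discretization step of the exact null (log2 units)


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass
class SnpWindow:
    """REF/ALT sequence windows around one index SNP."""

    snp_id: str
    seq_ref: str
    seq_alt: str
    snp_index: int

    def __post_init__(self):
        if len(self.seq_ref) != len(self.seq_alt):
            raise FormatError(f"{self.snp_id}: allele windows differ in length")
        i = self.snp_index
        if self.seq_ref[:i] != self.seq_alt[:i] or self.seq_ref[i + 1 :] != self.seq_alt[i + 1 :]:
            raise FormatError(f"{self.snp_id}: windows differ outside the SNP base")


@dataclass
class Pwm:
    """A PWM with per-position base probabilities (rows = positions)."""

    motif_id: str
    matrix: np.ndarray  # shape (L, 4), probabilities
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.25

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise FormatError(f"{self.motif_id}: matrix must be L x 4")
        if self.matrix.shape[0] < 2:
            raise FormatError(f"{self.motif_id}: PWM needs at least 2 positions")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise FormatError(f"{self.motif_id}: PWM columns do not sum to 1")
        self._cache: dict = {}

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_counts(cls, motif_id, counts, background=None, pseudocount=0.25):
        counts = np.asarray(counts, dtype=float) + pseudocount
        matrix = counts / counts.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background)
        return cls(motif_id, matrix, bg, pseudocount)

    @property
    def logratio(self) -> np.ndarray:
        """(L, 4) log2(p / background)."""
        return np.log2(self.matrix / self.background)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def score_window(self, window: str) -> float:
        """Log2 likelihood-ratio score of one L-length window (forward)."""
        lr = self.logratio
        if len(window) != len(self):
            raise FormatError("window length != motif length")
        return float(sum(lr[i, BASE_INDEX[b]] for i, b in enumerate(window.upper())))

    # -- exact nulls ------------------------------------------------------

    def _column_bins(self):
        """Integer grid offsets and background probs per column."""
        q = np.rint(self.logratio / GRID).astype(np.int64)
        return q, self.background

    def _convolve(self, columns):
        """Exact distribution of the sum of score contributions for the
        given column indices, bases drawn from the background."""
        q, bg = self._column_bins()
        dist = np.ones(1)
        offset = 0
        for j in columns:
            qs = q[j]
            shift = int(qs.min())
            width = int(qs.max() - qs.min())
            new = np.zeros(len(dist) + width)
            for b in range(4):
                new[qs[b] - shift : qs[b] - shift + len(dist)] += bg[b] * dist
            dist = new
            offset += shift
        return offset, dist

    def _null_full(self):
        if "full" not in self._cache:
            self._cache["full"] = self._convolve(range(len(self)))
        return self._cache["full"]

    def sf_single(self, score: float) -> float:
        """P(single-offset score >= score) under the background model."""
        offset, dist = self._null_full()
        # half-bin-per-column rounding slack keeps the tail conservative
        k = int(np.rint(score / GRID)) - offset - len(self)
        if k <= 0:
            return 1.0
        k = min(k, len(dist) - 1)
        return float(dist[k:].sum())

    def best_hit_p(self, score: float, n_alignments: int) -> float:
        """Sidak-combined P(best over n alignments >= score)."""
        p1 = self.sf_single(score)
        p = 1.0 - (1.0 - p1) ** n_alignments
        return max(p, np.finfo(float).tiny)

    def paired_diff_null(self, n: int = 2000, seed: int = 7) -> np.ndarray:
        """Sorted |best-hit score difference| null for a random biallelic
        substitution in background sequence.

        The two alleles share their flanking sequence (paired), so the
        null respects the fact that the best hit can shift alignment to
        dodge an unfavourable SNP base.  Null windows are 2L-1 long with
        the SNP at the center (every offset covers it); cached.
        """
        key = ("diffnull", n, seed)
        if key in self._cache:
            return self._cache[key]
        import zlib

        L = len(self)
        rng = np.random.Generator(
            np.random.PCG64(
                np.random.SeedSequence(
                    [seed, zlib.crc32(self.motif_id.encode()) % (2**32), n]
                )
            )
        )
        W = 2 * L - 1
        center = L - 1
        codes = rng.integers(0, 4, size=(n, W))
        lr = self.logratio
        lr_rc = lr[::-1, ::-1]  # reverse-complement motif scores
        best = np.full((4, n), -np.inf)
        for b in range(4):
            codes[:, center] = b
            for t in range(L):
                sub = codes[:, t : t + L]
                fwd = lr[np.arange(L), sub].sum(axis=1)
                rev = lr_rc[np.arange(L), sub].sum(axis=1)
                np.maximum(best[b], np.maximum(fwd, rev), out=best[b])
        pairs = rng.integers(0, 4, size=(n, 2))
        clash = pairs[:, 0] == pairs[:, 1]
        pairs[clash, 1] = (pairs[clash, 0] + 1 + rng.integers(0, 3, clash.sum())) % 4
        diffs = np.abs(best[pairs[:, 0], np.arange(n)] - best[pairs[:, 1], np.arange(n)])
        self._cache[key] = np.sort(diffs)
        return self._cache[key]

    def diff_p(self, obs_diff: float, n_null: int = 2000, seed: int = 7) -> float:
        """Empirical two-sided P(|score difference| >= |obs|) under the
        paired background null, with add-one smoothing."""
        null = self.paired_diff_null(n=n_null, seed=seed)
        k = len(null) - np.searchsorted(null, abs(obs_diff) - 1e-9, side="left")
        return float((1 + k) / (len(null) + 1))


# -- JASPAR I/O -----------------------------------------------------------


JASPAR_COUNT_SCALE = 100_000  # deep enough that the reader's pseudocount
# perturbs probabilities by < 1e-5 on round trip


def write_jaspar(pwms, path) -> None:
    """Write count-style JASPAR text (probabilities scaled to counts)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.motif_id}\n")
            for bi, base in enumerate(BASES):
                vals = " ".join(
                    f"{JASPAR_COUNT_SCALE * v:14.2f}" for v in pwm.matrix[:, bi]
                )
                fh.write(f"{base} [ {vals} ]\n")


def read_jaspar(path, pseudocount: float = 0.25):
    """Parse JASPAR-format PWMs via Bio.motifs; returns a list of Pwm."""
    try:
        with open(path) as fh:
            records = bio_motifs.parse(fh, "jaspar")
            out = []
            for rec in records:
                counts = np.array(
                    [[rec.counts[b][i] for b in BASES] for i in range(rec.length)]
                )
                out.append(
                    Pwm.from_counts(rec.matrix_id or rec.name, counts, pseudocount=pseudocount)
                )
    except (KeyError, ValueError, IndexError) as exc:
        raise FormatError(f"malformed JASPAR file {path}: {exc}") from exc
    if not out:
        raise FormatError(f"no motifs parsed from {path}")
    for pwm in out:
        if len(pwm) < 2:
            raise FormatError(f"{pwm.motif_id}: fewer than 2 PWM columns")
    return out
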