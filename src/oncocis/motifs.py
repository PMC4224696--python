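"""Position-weight-matrix scanning and motif gain/loss calling.

A motif is scored as a log-likelihood ratio in bits against a uniform
background::

    score = sum_k log2( q(k, seq_k) / 0.25 )

where ``q(k, b)`` is the base frequency at matrix position ``k``. No
pseudocounts are added, so a base with zero counts yields ``-inf`` and the
placement simply cannot be a hit. A placement qualifies when its score
exceeds the cutoff (default 5 bits) *and* every well-conserved matrix
position (a base at > 80% frequency) is matched exactly — the stringency
filter that keeps only near-consensus sites.

Both strands are scanned; the minus strand is scored on the reverse
complement of the window. Reported transcription-factor sets are
strand-agnostic and deduplicated by TF name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "PositionWeightMatrix",
    "MotifHit",
    "filter_motif_db",
    "pssm_score",
    "conserved_positions",
    "stringent_match",
    "build_windows",
    "scan",
    "scan_hits",
    "diff_motifs",
    "revcomp",
]

_BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")
_INDEX = {b: i for i, b in enumerate(_BASES)}


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


@dataclass(frozen=True)
class PositionWeightMatrix:
    """A TF binding motif as per-position base counts (rows A, C, G, T)."""

    name: str
    counts: np.ndarray  # shape (4, W)
    taxon: str = "unknown"
    matrix_id: Optional[str] = None

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError(f"{self.name}: counts must be a 4 x W matrix")
        if (counts < 0).any():
            raise ValueError(f"{self.name}: negative count")
        if (counts.sum(axis=0) <= 0).any():
            raise ValueError(f"{self.name}: empty matrix column")
        object.__setattr__(self, "counts", counts)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def n_sites(self) -> int:
        """Number of sequences contributing to the matrix (column total)."""
        return int(round(self.counts.sum(axis=0).max()))

    @property
    def q(self) -> np.ndarray:
        """Per-position base probabilities; columns sum to 1, zeros kept."""
        return self.counts / self.counts.sum(axis=0, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        """log2(q / 0.25) with -inf where q = 0 (no pseudocounts)."""
        q = self.q
        with np.errstate(divide="ignore"):
            return np.where(q > 0, np.log2(np.maximum(q, 1e-300) / 0.25), -np.inf)

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.q.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    tf_name: str
    offset: int  # 0-based start within the scanned window
    strand: str  # '+' or '-'
    score: float


def filter_motif_db(motifs: Sequence[PositionWeightMatrix],
                    taxon_filter: Iterable[str],
                    min_sites: int = 20) -> list[PositionWeightMatrix]:
    """Keep motifs whose taxon is in ``taxon_filter`` and which are backed
    by strictly more than ``min_sites`` sequences; input order preserved."""
    taxa = set(taxon_filter)
    return [m for m in motifs if m.taxon in taxa and m.n_sites > min_sites]


def pssm_score(motif: PositionWeightMatrix, seq: str) -> float:
    """Log-likelihood ratio of ``seq`` under the motif vs uniform background.

    ``seq`` must have length W; any base outside {A,C,G,T} (e.g. N) or a
    zero-frequency base scores -inf.
    """
    seq = seq.upper()
    if len(seq) != motif.width:
        raise ValueError(f"sequence length {len(seq)} != motif width {motif.width}")
    lo = motif.log_odds
    total = 0.0
    for k, b in enumerate(seq):
        i = _INDEX.get(b)
        if i is None:
            return float("-inf")
        v = lo[i, k]
        if v == float("-inf"):
            return float("-inf")
        total += v
    return total


def conserved_positions(motif: PositionWeightMatrix,
                        threshold: float = 0.8) -> set[tuple[int, str]]:
    """All (position, base) pairs with base frequency strictly above
    ``threshold``; positions are 0-based."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    q = motif.q
    return {(k, _BASES[i])
            for k in range(motif.width)
            for i in range(4)
            if q[i, k] > threshold}


def stringent_match(motif: PositionWeightMatrix, seq: str,
                    threshold: float = 0.8) -> bool:
    """True iff every well-conserved motif position matches ``seq`` exactly."""
    seq = seq.upper()
    if len(seq) != motif.width:
        raise ValueError(f"sequence length {len(seq)} != motif width {motif.width}")
    return all(seq[k] == b for k, b in conserved_positions(motif, threshold))


def build_windows(m, genome: Mapping[str, str], pad: int = 20) -> tuple[str, str]:
    """Wild-type and mutant sequence windows of +/- ``pad`` bp around a
    mutation.

    The wild-type window spans reference positions
    [pos - pad, pos + len(ref) - 1 + pad] (1-based closed, clipped to the
    chromosome); the mutant window has the same flanks with the reference
    allele replaced by the alternate — for indels the two windows differ
    in length. The reference allele is checked against the genome.
    """
    from .core import MutationKind

    if m.chrom not in genome:
        raise KeyError(f"chromosome {m.chrom} absent from genome")
    chrom_seq = genome[m.chrom].upper()
    n = len(chrom_seq)
    if m.kind is MutationKind.INSERTION:
        left = chrom_seq[max(0, m.pos - pad): m.pos]          # [pos-pad+1 .. pos]
        right = chrom_seq[m.pos: min(n, m.pos - 1 + pad)]      # [pos+1 .. pos-1+pad]
        return left + right, left + m.alt + right
    ref_start0 = m.pos - 1
    ref_end0 = ref_start0 + len(m.ref)
    if ref_end0 > n:
        raise ValueError(f"mutation {m.chrom}:{m.pos} runs off the chromosome end")
    observed = chrom_seq[ref_start0:ref_end0]
    if observed != m.ref:
        raise ValueError(f"reference mismatch at {m.chrom}:{m.pos}: genome has "
                         f"{observed!r}, mutation claims {m.ref!r}")
    left = chrom_seq[max(0, ref_start0 - pad): ref_start0]
    right = chrom_seq[ref_end0: min(n, ref_end0 + pad)]
    return left + observed + right, left + m.alt + right


def scan_hits(seq: str, motifs: Sequence[PositionWeightMatrix],
              cutoff: float = 5.0, threshold: float = 0.8) -> list[MotifHit]:
    """All qualifying placements of all motifs on both strands of ``seq``.

    A placement qualifies when its score strictly exceeds ``cutoff`` and
    the conserved-position filter matches. Minus-strand placements are
    scored on the reverse complement of the covered window.
    """
    seq = seq.upper()
    hits: list[MotifHit] = []
    for motif in motifs:
        w = motif.width
        for off in range(len(seq) - w + 1):
            window = seq[off:off + w]
            for strand, oriented in (("+", window), ("-", revcomp(window))):
                score = pssm_score(motif, oriented)
                if score > cutoff and stringent_match(motif, oriented, threshold):
                    hits.append(MotifHit(motif.name, off, strand, score))
    return hits


def scan(seq: str, motifs: Sequence[PositionWeightMatrix],
         cutoff: float = 5.0, threshold: float = 0.8) -> set[str]:
    """TF names with at least one qualifying placement in ``seq``."""
    return {h.tf_name for h in scan_hits(seq, motifs, cutoff, threshold)}


def diff_motifs(wt_hits: set[str], mut_hits: set[str]) -> tuple[set[str], set[str]]:
    """(created, removed) = (mutant-specific TFs, wild-type-specific TFs)."""
    return set(mut_hits) - set(wt_hits), set(wt_hits) - set(mut_hits)
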