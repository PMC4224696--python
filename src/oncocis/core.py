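"""Domain types and coordinate conventions.

Conventions used throughout the package:

* Mutations are expressed in 1-based coordinates (``pos`` is the first
  affected base), matching how positions are printed in the genomics
  literature (e.g. ``chr5:1,295,228``).
* All BED-derived intervals are 0-based half-open, the BED standard.
  Conversion between the two happens only inside query helpers.
* Deletions are anchored at the first deleted base; insertions at the
  base *after which* the inserted sequence goes.
* Chromosome names are normalized by adding a ``chr`` prefix when absent
  (ENCODE / Epigenome Atlas files use ``chr``); prefixes are never stripped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger("oncocis")

__all__ = [
    "MutationKind",
    "Mutation",
    "GenomicInterval",
    "PeakSet",
    "GeneModel",
    "EnhancerTssAssociation",
    "ConservationTrack",
    "ExpressionMatrix",
    "AnnotationRecord",
    "normalize_chrom",
]


def normalize_chrom(chrom: str) -> str:
    """Add a ``chr`` prefix if absent. Never strips an existing prefix."""
    chrom = chrom.strip()
    if not chrom:
        raise ValueError("empty chromosome name")
    return chrom if chrom.startswith("chr") else "chr" + chrom


class MutationKind(str, Enum):
    SUBSTITUTION = "substitution"
    INSERTION = "insertion"
    DELETION = "deletion"


@dataclass(frozen=True)
class Mutation:
    """A candidate somatic variant with its sample of origin.

    ``pos`` is 1-based and points at the first affected base. ``ref`` and
    ``alt`` must already be minimal (no shared leading context base): use
    :meth:`from_alleles` to build a Mutation from VCF-style anchored alleles.
    ``ref`` is empty for a pure insertion, ``alt`` empty for a pure deletion.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"mutation position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref!r}) at "
                             f"{self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if any(b not in "ACGTN" for b in allele.upper()):
                raise ValueError(f"invalid allele {allele!r} at {self.chrom}:{self.pos}")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())

    @property
    def kind(self) -> MutationKind:
        if len(self.ref) == len(self.alt) and len(self.ref) >= 1:
            return MutationKind.SUBSTITUTION
        if len(self.alt) < len(self.ref):
            return MutationKind.DELETION
        return MutationKind.INSERTION

    @classmethod
    def from_alleles(cls, chrom: str, pos: int, ref: str, alt: str,
                     sample_id: str) -> "Mutation":
        """Build from VCF-style alleles, trimming shared leading bases.

        ``chr1 100 AT A`` becomes a 1-base deletion anchored at 101;
        ``chr1 100 A AT`` an insertion anchored after base 100.
        """
        ref, alt = ref.upper(), alt.upper()
        if ref == alt:
            raise ValueError(f"ref and alt identical at {chrom}:{pos}")
        while ref and alt and ref[0] == alt[0] and (len(ref) > 1 or len(alt) > 1):
            # keep at least one base on the longer side; anchor advances
            if len(ref) == 1 and len(alt) == 1:
                break
            ref, alt = ref[1:], alt[1:]
            pos += 1
        if not ref:
            pos -= 1  # insertion anchored at the base after which it occurs
        return cls(chrom, pos, ref, alt, sample_id)

    @property
    def affected_span(self) -> tuple[int, int]:
        """1-based closed span of reference bases touched (anchor base for
        insertions)."""
        if self.kind is MutationKind.INSERTION:
            return (self.pos, self.pos)
        return (self.pos, self.pos + len(self.ref) - 1)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos} {self.ref or '-'}>{self.alt or '-'} [{self.sample_id}]"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval, BED semantics."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = field(default=None, compare=False)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    def contains_point(self, pos1: int) -> bool:
        """Containment of a 1-based position: bases start+1 .. end."""
        return self.start < pos1 <= self.end

    @property
    def midpoint1(self) -> int:
        """1-based midpoint, floor((start+end)/2) converted to 1-based."""
        return (self.start + self.end) // 2

    def extended(self, pad: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, max(0, self.start - pad),
                               self.end + pad, self.name)


class PeakSet:
    """A named collection of genomic intervals with point/interval queries.

    Backed by one interval tree per chromosome; chromosomes are independent.
    """

    MARKS = {"DHS", "H3K4me1", "H3K4me3", "H3K27ac", "promoter", "enhancer", "other"}

    def __init__(self, mark: str, intervals: Iterable[GenomicInterval] = ()):
        if mark not in self.MARKS:
            raise ValueError(f"unknown mark {mark!r}; expected one of {sorted(self.MARKS)}")
        self.mark = mark
        self._trees: dict[str, IntervalTree] = {}
        self._intervals: list[GenomicInterval] = []
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        # payload carries an insertion index so duplicate peaks survive
        # the tree's set semantics
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end, (len(self._intervals), iv))
        self._intervals.append(iv)

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self):
        return iter(self._intervals)

    def query_point(self, chrom: str, pos1: int) -> list[GenomicInterval]:
        """Intervals containing the 1-based position, sorted by (start, end)."""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return []
        hits = sorted(h.data for h in tree.at(pos1 - 1))
        return [iv for _, iv in sorted(hits, key=lambda d: (d[1].start, d[1].end))]

    def query_interval(self, chrom: str, start0: int, end0: int) -> list[GenomicInterval]:
        """Intervals overlapping [start0, end0) by >= 1 base."""
        if end0 <= start0:
            return []
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return []
        hits = sorted(h.data for h in tree.overlap(start0, end0))
        return [iv for _, iv in sorted(hits, key=lambda d: (d[1].start, d[1].end))]


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to symbol, strand and 1-based TSS."""

    symbol: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self):
        if self.tss < 1:
            raise ValueError(f"TSS must be >= 1 for {self.symbol}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-' for {self.symbol}")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))


@dataclass(frozen=True)
class EnhancerTssAssociation:
    """A transcribed-enhancer -> promoter pairing (CAGE-correlation style)."""

    enhancer: GenomicInterval
    gene_symbol: str


class ConservationTrack:
    """Per-base conservation probabilities in [0, 1] (phastCons-like).

    Missing positions are allowed; lookups return None for uncovered bases.
    """

    def __init__(self):
        self._scores: dict[str, dict[int, float]] = {}

    def set_range(self, chrom: str, start0: int, end0: int, score: float) -> None:
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"conservation score {score} outside [0, 1]")
        chrom = normalize_chrom(chrom)
        per = self._scores.setdefault(chrom, {})
        for pos1 in range(start0 + 1, end0 + 1):
            if pos1 in per:
                raise ValueError(f"overlapping conservation records at {chrom}:{pos1}")
            per[pos1] = score

    def get(self, chrom: str, pos1: int) -> Optional[float]:
        return self._scores.get(normalize_chrom(chrom), {}).get(pos1)

    def window_scores(self, chrom: str, start1: int, end1: int) -> list[float]:
        """Scores of covered bases in the 1-based closed window."""
        per = self._scores.get(normalize_chrom(chrom), {})
        return [per[p] for p in range(max(1, start1), end1 + 1) if p in per]

    def __len__(self) -> int:
        return sum(len(v) for v in self._scores.values())


class ExpressionMatrix:
    """Gene-by-sample expression values plus a set of flagged normal samples.

    A thin wrapper over a pandas DataFrame (genes as rows, samples as
    columns); missing cells are NaN and are dropped per-comparison
    downstream, never imputed.
    """

    def __init__(self, values: pd.DataFrame, normal_samples: Iterable[str] = ()):
        if values.columns.duplicated().any():
            raise ValueError("duplicate sample IDs in expression matrix")
        if values.index.duplicated().any():
            raise ValueError("duplicate gene symbols in expression matrix")
        normal = set(normal_samples)
        unknown = normal - set(values.columns)
        if unknown:
            raise ValueError(f"normal sample(s) absent from expression matrix: {sorted(unknown)}")
        self.values = values.astype(float)
        self.normal_samples = normal

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def get(self, gene: str, sample: str) -> Optional[float]:
        try:
            v = self.values.at[gene, sample]
        except KeyError:
            return None
        return None if pd.isna(v) else float(v)

    def sample_values(self, gene: str, samples: Sequence[str]) -> np.ndarray:
        """Expression of one gene across samples, NaNs dropped."""
        if gene not in self.values.index:
            return np.array([])
        row = self.values.loc[gene, [s for s in samples if s in self.values.columns]]
        return row.dropna().to_numpy(dtype=float)


@dataclass
class AnnotationRecord:
    """One mutation-gene annotation row (the unit of the output table)."""

    mutation: Mutation
    gene: Optional[str] = None
    distance_to_tss: Optional[int] = None
    in_dhs: bool = False
    dhs_interval: Optional[GenomicInterval] = None
    h3k4me1: bool = False
    h3k4me3: bool = False
    h3k27ac: bool = False
    conservation: Optional[float] = None
    background_conservation: Optional[float] = None
    motifs_created: frozenset[str] = frozenset()
    motifs_removed: frozenset[str] = frozenset()
    fantom_promoter: bool = False
    fantom_enhancer: bool = False
    fold_change: Optional[float] = None
    p_value: Optional[float] = None
    adj_p_value: Optional[float] = None

    def __post_init__(self):
        self.motifs_created = frozenset(self.motifs_created)
        self.motifs_removed = frozenset(self.motifs_removed)
        if self.motifs_created & self.motifs_removed:
            raise ValueError("a motif cannot be both created and removed")
        if (self.p_value is not None and self.adj_p_value is not None
                and self.adj_p_value < self.p_value - 1e-12):
            raise ValueError("adjusted p-value below raw p-value")
        if self.conservation is not None and self.mutation.kind is MutationKind.INSERTION:
            raise ValueError("insertions carry no conservation value")

    @property
    def has_motif_change(self) -> bool:
        return bool(self.motifs_created or self.motifs_removed)
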