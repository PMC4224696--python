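"""DHS membership and flanking-histone-mark annotation.

A mutation inside a DNase I hypersensitive site marks open chromatin;
histone peaks (H3K4me1 / H3K4me3 / H3K27ac) are sought not at the
mutation itself but in a flanking annulus 150-500 bp either side of an
anchor: the DHS peak center when the mutation sits in a DHS, otherwise
the mutation position. Any overlap (>= 1 base) between a histone peak
interval and either flank window counts — peak calls are broad, so
requiring the peak center inside the 351-bp ring would miss obviously
flanking peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .core import GenomicInterval, Mutation, MutationKind, PeakSet

__all__ = ["FlankWindows", "dhs_hit", "flank_anchor", "histone_flanking"]

FLANK_INNER_DEFAULT = 150
FLANK_OUTER_DEFAULT = 500


@dataclass(frozen=True)
class FlankWindows:
    """The two closed 1-based windows [anchor-outer, anchor-inner] and
    [anchor+inner, anchor+outer] around an anchor coordinate.

    A degenerate annulus (inner >= outer) is empty: both windows vanish.
    """

    anchor: int
    inner: int = FLANK_INNER_DEFAULT
    outer: int = FLANK_OUTER_DEFAULT

    @property
    def empty(self) -> bool:
        return self.inner >= self.outer

    @property
    def left(self) -> Optional[tuple[int, int]]:
        if self.empty:
            return None
        return (self.anchor - self.outer, self.anchor - self.inner)

    @property
    def right(self) -> Optional[tuple[int, int]]:
        if self.empty:
            return None
        return (self.anchor + self.inner, self.anchor + self.outer)


def dhs_hit(m: Mutation, dhs: PeakSet) -> Optional[GenomicInterval]:
    """The DHS interval containing the mutation, or None.

    For deletions any deleted base inside the peak counts; for insertions
    the anchor base counts. Ties (book-ended or duplicate peaks) resolve
    to the smallest start.
    """
    if dhs.mark != "DHS":
        raise ValueError(f"expected a DHS peak set, got mark {dhs.mark!r}")
    start1, end1 = m.affected_span
    hits = dhs.query_interval(m.chrom, start1 - 1, end1)
    return hits[0] if hits else None


def flank_anchor(m: Mutation, dhs_interval: Optional[GenomicInterval]) -> int:
    """Anchor for the flank windows: DHS peak center (floor midpoint,
    1-based) when the mutation is in a DHS, else the mutation position."""
    if dhs_interval is not None:
        return dhs_interval.midpoint1
    return m.pos


def histone_flanking(anchor: int, marks: PeakSet,
                     inner: int = FLANK_INNER_DEFAULT,
                     outer: int = FLANK_OUTER_DEFAULT,
                     chrom: Optional[str] = None) -> bool:
    """True iff any peak overlaps either flank window by >= 1 base.

    ``chrom`` defaults to the single chromosome of the peak set when
    unambiguous; pass it explicitly for multi-chromosome sets.
    """
    if marks.mark not in ("H3K4me1", "H3K4me3", "H3K27ac"):
        raise ValueError(f"expected a histone mark peak set, got {marks.mark!r}")
    if chrom is None:
        chroms = {iv.chrom for iv in marks}
        if len(chroms) != 1:
            raise ValueError("chrom required for a multi-chromosome peak set")
        chrom = chroms.pop()
    win = FlankWindows(anchor, inner, outer)
    if win.empty:
        return False
    for bounds in (win.left, win.right):
        lo1, hi1 = bounds
        # closed 1-based [lo1, hi1] -> half-open 0-based [lo1-1, hi1)
        if hi1 < 1:
            continue
        if marks.query_interval(chrom, max(0, lo1 - 1), hi1):
            return True
    return False
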