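"""Target-gene assignment and promoter/enhancer-transcript flags.

A mutation inside a transcribed enhancer that has a CAGE-derived
association with a gene's TSS is assigned to that gene (one record per
associated gene); otherwise it falls back to the nearest TSS within
1 Mbp. Distances to the TSS are signed in the gene's orientation:
negative upstream, positive downstream, 0 at the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .core import EnhancerTssAssociation, GeneModel, Mutation, PeakSet

__all__ = ["GeneAssignment", "distance_to_tss", "map_to_gene", "fantom_flags"]

MAX_GENE_DIST_DEFAULT = 1_000_000
FANTOM_EXTENSION_DEFAULT = 500


@dataclass(frozen=True)
class GeneAssignment:
    gene: Optional[GeneModel]
    source: str  # enhancer_association | nearest_tss | none
    distance_to_tss: Optional[int]


def distance_to_tss(m: Mutation, g: GeneModel) -> int:
    """Signed distance from the mutation anchor base to the TSS, in the
    gene's orientation (negative = upstream)."""
    if m.chrom != g.chrom:
        raise ValueError(f"mutation on {m.chrom} but gene {g.symbol} on {g.chrom}")
    return m.pos - g.tss if g.strand == "+" else g.tss - m.pos


def map_to_gene(m: Mutation,
                assoc: Sequence[EnhancerTssAssociation],
                genes: Sequence[GeneModel],
                max_dist: int = MAX_GENE_DIST_DEFAULT) -> list[GeneAssignment]:
    """Assign the mutation to its most likely target gene(s).

    Enhancer-TSS associations take priority: a mutation inside several
    associated enhancers maps to every associated gene. With no
    association the nearest TSS on the same chromosome within
    ``max_dist`` wins; ties break by smaller |distance| then gene symbol.
    Returns [GeneAssignment(None, 'none', None)] when nothing qualifies.
    """
    by_symbol = {g.symbol: g for g in genes}
    assigned: dict[str, GeneAssignment] = {}
    for a in assoc:
        if a.enhancer.chrom == m.chrom and a.enhancer.contains_point(m.pos):
            g = by_symbol.get(a.gene_symbol)
            dist = (distance_to_tss(m, g)
                    if g is not None and g.chrom == m.chrom else None)
            assigned.setdefault(a.gene_symbol, GeneAssignment(g, "enhancer_association", dist))
    if assigned:
        return [assigned[s] for s in sorted(assigned)]

    candidates = [(abs(distance_to_tss(m, g)), g.symbol, g)
                  for g in genes if g.chrom == m.chrom]
    candidates = [c for c in candidates if c[0] <= max_dist]
    if not candidates:
        return [GeneAssignment(None, "none", None)]
    _, _, best = min(candidates)
    return [GeneAssignment(best, "nearest_tss", distance_to_tss(m, best))]


def fantom_flags(m: Mutation, promoters: PeakSet, enhancers: PeakSet,
                 extension: int = FANTOM_EXTENSION_DEFAULT) -> tuple[bool, bool]:
    """(promoter, enhancer) transcript overlap after symmetric extension.

    Transcript predictions locate the transcript rather than the element
    itself, so each interval is widened by ``extension`` bp on both sides
    before testing the mutation position.
    """
    def hit(peaks: PeakSet) -> bool:
        lo0 = max(0, m.pos - 1 - extension)
        hi0 = m.pos + extension
        return any(True for _ in peaks.query_interval(m.chrom, lo0, hi0))

    return hit(promoters), hit(enhancers)
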