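"""Per-mutation conservation and local background conservation.

Substitutions report the phastCons-style score of the mutated base
(multi-base substitutions: the mean over substituted bases); deletions
the mean over deleted bases; insertions report nothing, as no reference
base is altered. A background value is the mean over all covered bases
within +/- 20 bp of the mutation. Bases missing from the track are
excluded from means rather than treated as zero — conservation tracks
have gaps, and zero-filling would bias scores downward.
"""

from __future__ import annotations

import logging
from typing import Optional

from .core import ConservationTrack, Mutation, MutationKind

logger = logging.getLogger("oncocis")

__all__ = ["mutation_conservation", "background_conservation"]

BACKGROUND_PAD_DEFAULT = 20


def mutation_conservation(m: Mutation, track: ConservationTrack) -> Optional[float]:
    """Conservation of the mutated base(s); None for insertions or when
    every affected base is missing from the track."""
    if m.kind is MutationKind.INSERTION:
        return None
    start1, end1 = m.affected_span
    scores = track.window_scores(m.chrom, start1, end1)
    if not scores:
        logger.warning("no conservation coverage for %s", m)
        return None
    return sum(scores) / len(scores)


def background_conservation(m: Mutation, track: ConservationTrack,
                            pad: int = BACKGROUND_PAD_DEFAULT) -> Optional[float]:
    """Mean conservation over covered bases within +/- ``pad`` bp of the
    mutation site (the mutated base included); None if nothing is covered."""
    scores = track.window_scores(m.chrom, m.pos - pad, m.pos + pad)
    if not scores:
        logger.warning("no conservation coverage in +/-%d bp of %s", pad, m)
        return None
    return sum(scores) / len(scores)
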