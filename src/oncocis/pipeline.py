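"""End-to-end annotation run: chromatin context, motif gain/loss, gene
assignment, conservation, promoter/enhancer transcription flags, and
(optionally) mutation-linked differential expression, followed by the
prioritization filter.

Prioritized records are those with all of: a DHS, a flanking H3K4me1 or
H3K4me3 mark, conservation of the mutated base(s) > 0.8, at least one
motif created or removed, and adjusted differential-expression p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import io as ocio
from .conservation import (BACKGROUND_PAD_DEFAULT, background_conservation,
                           mutation_conservation)
from .core import (AnnotationRecord, ConservationTrack,
                   EnhancerTssAssociation, ExpressionMatrix, GeneModel,
                   Mutation, PeakSet)
from .epigenome import (FLANK_INNER_DEFAULT, FLANK_OUTER_DEFAULT, dhs_hit,
                        flank_anchor, histone_flanking)
from .expression import adjust, classify_samples, de_test, fold_change
from .genes import (FANTOM_EXTENSION_DEFAULT, MAX_GENE_DIST_DEFAULT,
                    fantom_flags, map_to_gene)
from .motifs import (PositionWeightMatrix, build_windows, diff_motifs,
                     filter_motif_db, scan)

logger = logging.getLogger("oncocis")

__all__ = ["RunConfig", "RunSummary", "annotate_all", "prioritize", "summarize"]

MAMMALIAN_TAXA = frozenset({"mammals", "vertebrates"})


@dataclass
class RunConfig:
    """All inputs and thresholds for one annotation run.

    Loaded in-memory objects take precedence over paths; paths are read
    lazily at run start so the CLI and the library share one entry point.
    """

    mutations: Sequence[Mutation] = ()
    genome: dict = field(default_factory=dict)
    dhs: Optional[PeakSet] = None
    h3k4me1: Optional[PeakSet] = None
    h3k4me3: Optional[PeakSet] = None
    h3k27ac: Optional[PeakSet] = None
    motifs: Sequence[PositionWeightMatrix] = ()
    conservation: Optional[ConservationTrack] = None
    genes: Sequence[GeneModel] = ()
    enhancer_tss: Sequence[EnhancerTssAssociation] = ()
    fantom_promoters: Optional[PeakSet] = None
    fantom_enhancers: Optional[PeakSet] = None
    expression: Optional[ExpressionMatrix] = None
    coding_mask: Optional[PeakSet] = None
    cell_type: str = "user"

    motif_cutoff: float = 5.0
    conserved_threshold: float = 0.8
    window_pad: int = 20
    min_motif_sites: int = 20
    taxon_filter: frozenset = MAMMALIAN_TAXA
    flank_inner: int = FLANK_INNER_DEFAULT
    flank_outer: int = FLANK_OUTER_DEFAULT
    max_gene_dist: int = MAX_GENE_DIST_DEFAULT
    fantom_extension: int = FANTOM_EXTENSION_DEFAULT
    background_pad: int = BACKGROUND_PAD_DEFAULT
    prioritize_conservation: float = 0.8
    prioritize_adj_p: float = 0.05

    @classmethod
    def from_paths(cls, mutations, genome, dhs, h3k4me1, h3k4me3, h3k27ac,
                   motifs, conservation, genes, enhancer_tss,
                   fantom_promoters, fantom_enhancers, expression=None,
                   normal_samples=(), coding_mask=None, mutation_dialect="tsv",
                   **thresholds) -> "RunConfig":
        def bed(p, mark):
            return ocio.read_bed(p, mark) if p else None

        return cls(
            mutations=ocio.read_mutations(mutations, dialect=mutation_dialect),
            genome=ocio.read_genome(genome) if genome else {},
            dhs=bed(dhs, "DHS"),
            h3k4me1=bed(h3k4me1, "H3K4me1"),
            h3k4me3=bed(h3k4me3, "H3K4me3"),
            h3k27ac=bed(h3k27ac, "H3K27ac"),
            motifs=ocio.read_pfm(motifs) if motifs else (),
            conservation=ocio.read_conservation(conservation) if conservation else None,
            genes=ocio.read_gene_models(genes) if genes else (),
            enhancer_tss=ocio.read_enhancer_tss(enhancer_tss) if enhancer_tss else (),
            fantom_promoters=bed(fantom_promoters, "promoter"),
            fantom_enhancers=bed(fantom_enhancers, "enhancer"),
            expression=(ocio.read_expression(expression, normal_samples)
                        if expression else None),
            coding_mask=bed(coding_mask, "other"),
            **thresholds,
        )


@dataclass
class RunSummary:
    total: int = 0
    non_coding: Optional[int] = None
    in_dhs: int = 0
    flanking_h3k4me1: int = 0
    flanking_h3k4me3: int = 0
    flanking_h3k27ac: int = 0
    with_motif_change: int = 0
    prioritized: int = 0

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _is_coding(m: Mutation, mask: Optional[PeakSet]) -> bool:
    if mask is None:
        return False
    s1, e1 = m.affected_span
    return bool(mask.query_interval(m.chrom, s1 - 1, e1))


def annotate_all(config: RunConfig) -> tuple[list[AnnotationRecord], RunSummary]:
    """Annotate every mutation through all stages.

    Differential expression runs only when an expression matrix is
    supplied and the mutation is inside a DHS with a gene assigned.
    Output order is deterministic: (chrom, pos, sample, gene).
    """
    motif_db = filter_motif_db(config.motifs, config.taxon_filter,
                               config.min_motif_sites) if config.motifs else []
    records: list[AnnotationRecord] = []
    stage1 = []  # (mutation, base annotation fields, assignments)
    mutations = [m for m in config.mutations
                 if not _is_coding(m, config.coding_mask)]

    for m in mutations:
        dhs_iv = dhs_hit(m, config.dhs) if config.dhs is not None else None
        anchor = flank_anchor(m, dhs_iv)
        flags = {}
        for name, peaks in (("h3k4me1", config.h3k4me1),
                            ("h3k4me3", config.h3k4me3),
                            ("h3k27ac", config.h3k27ac)):
            flags[name] = (histone_flanking(anchor, peaks, config.flank_inner,
                                            config.flank_outer, chrom=m.chrom)
                           if peaks is not None and len(peaks) else False)

        created: set[str] = set()
        removed: set[str] = set()
        if motif_db and m.chrom in config.genome:
            try:
                wt, mut = build_windows(m, config.genome, config.window_pad)
            except ValueError as exc:
                logger.warning("motif stage skipped for %s: %s", m, exc)
            else:
                wt_hits = scan(wt, motif_db, config.motif_cutoff,
                               config.conserved_threshold)
                mut_hits = scan(mut, motif_db, config.motif_cutoff,
                                config.conserved_threshold)
                created, removed = diff_motifs(wt_hits, mut_hits)

        cons = bg = None
        if config.conservation is not None:
            cons = mutation_conservation(m, config.conservation)
            bg = background_conservation(m, config.conservation,
                                         config.background_pad)

        if config.fantom_promoters is not None or config.fantom_enhancers is not None:
            empty = PeakSet("other")
            prom_flag, enh_flag = fantom_flags(
                m, config.fantom_promoters or empty,
                config.fantom_enhancers or empty, config.fantom_extension)
        else:
            prom_flag = enh_flag = False

        assignments = map_to_gene(m, config.enhancer_tss, config.genes,
                                  config.max_gene_dist)
        stage1.append((m, dhs_iv, flags, created, removed, cons, bg,
                       prom_flag, enh_flag, assignments))

    # Bonferroni family size: distinct DHS-associated (mutation, gene) records
    n_tests = sum(1 for (m, dhs_iv, *_rest, assignments) in stage1
                  if dhs_iv is not None
                  for a in assignments if a.gene is not None)

    for (m, dhs_iv, flags, created, removed, cons, bg,
         prom_flag, enh_flag, assignments) in stage1:
        for a in assignments:
            fc = p = adj = None
            if (config.expression is not None and dhs_iv is not None
                    and a.gene is not None):
                mutant_ids, non_ids = classify_samples(dhs_iv, mutations,
                                                       config.expression)
                if m.sample_id in mutant_ids:
                    non_vals = config.expression.sample_values(a.gene.symbol, non_ids)
                    mv = config.expression.get(a.gene.symbol, m.sample_id)
                    if mv is not None and len(non_vals):
                        fc = fold_change(mv, non_vals)
                        p, _degen = de_test(mv, non_vals)
                        if p is not None and n_tests >= 1:
                            adj = adjust(p, n_tests)
            records.append(AnnotationRecord(
                mutation=m,
                gene=a.gene.symbol if a.gene is not None else None,
                distance_to_tss=a.distance_to_tss,
                in_dhs=dhs_iv is not None,
                dhs_interval=dhs_iv,
                h3k4me1=flags["h3k4me1"], h3k4me3=flags["h3k4me3"],
                h3k27ac=flags["h3k27ac"],
                conservation=cons, background_conservation=bg,
                motifs_created=frozenset(created),
                motifs_removed=frozenset(removed),
                fantom_promoter=prom_flag, fantom_enhancer=enh_flag,
                fold_change=fc, p_value=p, adj_p_value=adj,
            ))

    records.sort(key=lambda r: (r.mutation.chrom, r.mutation.pos,
                                r.mutation.sample_id, r.gene or ""))
    summary = summarize(records,
                        non_coding=len(mutations) if config.coding_mask is not None else None,
                        total=len(config.mutations), config=config)
    return records, summary


def prioritize(records: Sequence[AnnotationRecord],
               conservation_threshold: float = 0.8,
               adj_p_threshold: float = 0.05) -> list[AnnotationRecord]:
    """Records passing all prioritization criteria: in a DHS, flanking
    H3K4me1 or H3K4me3, conservation strictly > 0.8, >= 1 motif created
    or removed, and adjusted p strictly < 0.05."""
    out = []
    for r in records:
        if not r.in_dhs:
            continue
        if not (r.h3k4me1 or r.h3k4me3):
            continue
        if r.conservation is None or r.conservation <= conservation_threshold:
            continue
        if not r.has_motif_change:
            continue
        if r.adj_p_value is None or r.adj_p_value >= adj_p_threshold:
            continue
        out.append(r)
    return out


def summarize(records: Sequence[AnnotationRecord],
              non_coding: Optional[int] = None,
              total: Optional[int] = None,
              config: Optional[RunConfig] = None) -> RunSummary:
    """Per-mutation summary counts (a mutation with several gene
    assignments is counted once)."""
    def key(r):
        m = r.mutation
        return (m.chrom, m.pos, m.ref, m.alt, m.sample_id)

    seen: dict = {}
    for r in records:
        seen.setdefault(key(r), r)
    uniq = list(seen.values())
    cons_thr = config.prioritize_conservation if config else 0.8
    adj_thr = config.prioritize_adj_p if config else 0.05
    prioritized_keys = {key(r) for r in prioritize(records, cons_thr, adj_thr)}
    return RunSummary(
        total=total if total is not None else len(uniq),
        non_coding=non_coding,
        in_dhs=sum(r.in_dhs for r in uniq),
        flanking_h3k4me1=sum(r.h3k4me1 for r in uniq),
        flanking_h3k4me3=sum(r.h3k4me3 for r in uniq),
        flanking_h3k27ac=sum(r.h3k27ac for r in uniq),
        with_motif_change=sum(r.has_motif_change for r in uniq),
        prioritized=len(prioritized_keys),
    )
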