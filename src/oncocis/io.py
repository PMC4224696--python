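"""Readers and writers for the file formats the pipeline touches.

Mutations come in as TSV (chrom, pos, ref, alt, sample) or VCF 4.x;
peaks and regulatory elements as BED3+; motifs as JASPAR-style count
matrices (with an optional ``taxon=`` tag on the header line); per-base
conservation as bedGraph or fixed/variable-step wiggle; expression as a
gene-by-sample TSV. All readers reject malformed records with the
offending line number rather than silently coercing.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    AnnotationRecord,
    ConservationTrack,
    EnhancerTssAssociation,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    Mutation,
    PeakSet,
    normalize_chrom,
)
from .motifs import PositionWeightMatrix

logger = logging.getLogger("oncocis")

__all__ = [
    "read_mutations",
    "read_bed",
    "read_gene_models",
    "read_enhancer_tss",
    "read_pfm",
    "read_conservation",
    "read_expression",
    "read_genome",
    "write_annotations",
    "read_annotations",
    "ANNOTATION_COLUMNS",
]


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_mutations(path, dialect: str = "tsv", sample_info_key: str = "SAMPLE",
                   default_sample: str = "sample1") -> list[Mutation]:
    """Read candidate mutations from TSV or VCF.

    TSV rows need >= 5 columns: chrom, 1-based pos, ref, alt, sample.
    ``-`` or ``.`` denote an empty allele (pure insertion/deletion).
    VCF rows with multiple ALT alleles are expanded to one Mutation each;
    the sample label is taken from INFO[``sample_info_key``], falling back
    to genotype carriers, then ``default_sample``.
    """
    path = Path(path)
    if dialect == "vcf":
        return _read_mutations_vcf(path, sample_info_key, default_sample)
    if dialect != "tsv":
        raise ValueError(f"unknown mutation dialect {dialect!r}")
    muts: list[Mutation] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 5:
            raise ValueError(f"{path}:{lineno}: expected >=5 columns "
                             f"(chrom, pos, ref, alt, sample), got {len(fields)}")
        chrom, pos_s, ref, alt, sample = fields[:5]
        try:
            pos = int(pos_s.replace(",", ""))
        except ValueError:
            raise ValueError(f"{path}:{lineno}: position {pos_s!r} is not an integer")
        if pos < 1:
            raise ValueError(f"{path}:{lineno}: position must be a positive integer")
        ref = "" if ref in ("-", ".") else ref
        alt = "" if alt in ("-", ".") else alt
        try:
            if ref and alt:
                muts.append(Mutation.from_alleles(chrom, pos, ref, alt, sample))
            else:
                muts.append(Mutation(chrom, pos, ref, alt, sample))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not muts:
        logger.warning("no mutations read from %s", path)
    return muts


def _read_mutations_vcf(path: Path, sample_info_key: str,
                        default_sample: str) -> list[Mutation]:
    import pysam

    muts: list[Mutation] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if sample_info_key in rec.info:
                val = rec.info[sample_info_key]
                samples = [val if isinstance(val, str) else str(val[0])]
            else:
                carriers = [name for name, sm in rec.samples.items()
                            if any(a not in (0, None) for a in (sm.get("GT") or ()))]
                samples = carriers or [default_sample]
            for alt in rec.alts or ():
                for sample in samples:
                    muts.append(Mutation.from_alleles(rec.chrom, rec.pos,
                                                      rec.ref, alt, sample))
    if not muts:
        logger.warning("no mutations read from %s", path)
    return muts


def read_bed(path, mark: str = "other") -> PeakSet:
    """Read a BED3+ file into a PeakSet (0-based half-open, standard BED)."""
    path = Path(path)
    peaks = PeakSet(mark)
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-integer BED coordinates")
        if start >= end:
            raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
        name = fields[3] if len(fields) > 3 else None
        peaks.add(GenomicInterval(chrom, start, end, name))
    return peaks


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from 6-column BED; TSS is the strand-aware start
    (chromStart for '+', chromEnd for '-'), converted to 1-based."""
    path = Path(path)
    genes: list[GeneModel] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 6:
            raise ValueError(f"{path}:{lineno}: gene BED needs 6 columns "
                             "(chrom start end name score strand)")
        chrom, start_s, end_s, symbol, _score, strand = fields[:6]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates")
        if start >= end:
            raise ValueError(f"{path}:{lineno}: start >= end")
        if strand not in ("+", "-"):
            raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
        tss = start + 1 if strand == "+" else end
        genes.append(GeneModel(symbol, chrom, tss, strand))
    return genes


def read_enhancer_tss(path) -> list[EnhancerTssAssociation]:
    """Read enhancer-TSS associations: BED3 of the enhancer plus a gene
    symbol in column 4."""
    path = Path(path)
    assocs: list[EnhancerTssAssociation] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: need chrom, start, end, gene")
        chrom, start_s, end_s, gene = fields[:4]
        try:
            iv = GenomicInterval(chrom, int(start_s), int(end_s), gene)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        assocs.append(EnhancerTssAssociation(iv, gene))
    return assocs


def read_pfm(path) -> list[PositionWeightMatrix]:
    """Read JASPAR-style count matrices.

    Each record is a ``>ID NAME [taxon=TAG]`` header followed by four rows
    of per-position counts in A, C, G, T order, with or without the
    bracketed JASPAR row syntax (``A [ 4 19 0 ]``).
    """
    path = Path(path)
    motifs: list[PositionWeightMatrix] = []
    header: Optional[tuple[int, str]] = None
    rows: list[list[float]] = []

    def flush():
        nonlocal header, rows
        if header is None:
            return
        lineno, head = header
        if len(rows) != 4:
            raise ValueError(f"{path}:{lineno}: motif record needs 4 count rows, "
                             f"got {len(rows)}")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise ValueError(f"{path}:{lineno}: count rows of unequal width {sorted(widths)}")
        tokens = head[1:].split()
        name = tokens[1] if len(tokens) > 1 and "=" not in tokens[1] else tokens[0]
        taxon = "unknown"
        for tok in tokens:
            if tok.startswith("taxon="):
                taxon = tok.split("=", 1)[1]
        motifs.append(PositionWeightMatrix(name=name, counts=np.array(rows, dtype=float),
                                           taxon=taxon, matrix_id=tokens[0]))
        header, rows = None, []

    order = "ACGT"
    for lineno, line in _data_lines(path):
        if line.startswith(">"):
            flush()
            header = (lineno, line)
            continue
        if header is None:
            raise ValueError(f"{path}:{lineno}: counts before any '>' header")
        body = line
        if body and body.lstrip()[0].upper() in order and len(rows) < 4:
            stripped = body.lstrip()
            base = stripped[0].upper()
            if base != order[len(rows)]:
                raise ValueError(f"{path}:{lineno}: expected row for "
                                 f"{order[len(rows)]}, got {base}")
            body = stripped[1:]
        body = body.replace("[", " ").replace("]", " ")
        try:
            counts = [float(tok) for tok in body.split()]
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric count")
        if any(c < 0 for c in counts):
            raise ValueError(f"{path}:{lineno}: negative count")
        if not counts:
            raise ValueError(f"{path}:{lineno}: empty count row")
        rows.append(counts)
    flush()
    return motifs


def read_conservation(path) -> ConservationTrack:
    """Read a per-base conservation track from bedGraph or wiggle text.

    Supports 4-column bedGraph (0-based half-open), ``fixedStep`` and
    ``variableStep`` wiggle blocks. Scores must lie in [0, 1]; overlapping
    records are rejected as an ill-formed track.
    """
    path = Path(path)
    track = ConservationTrack()
    mode = "bedgraph"
    chrom = None
    step = span = 1
    nextpos = None  # 1-based, for fixedStep
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            try:
                if line.startswith("fixedStep"):
                    opts = dict(tok.split("=") for tok in line.split()[1:])
                    mode, chrom = "fixed", normalize_chrom(opts["chrom"])
                    nextpos = int(opts["start"])
                    step = int(opts.get("step", 1))
                    span = int(opts.get("span", 1))
                    continue
                if line.startswith("variableStep"):
                    opts = dict(tok.split("=") for tok in line.split()[1:])
                    mode, chrom = "variable", normalize_chrom(opts["chrom"])
                    span = int(opts.get("span", 1))
                    continue
                fields = line.split()
                if mode == "fixed":
                    score = float(fields[0])
                    track.set_range(chrom, nextpos - 1, nextpos - 1 + span, score)
                    nextpos += step
                elif mode == "variable":
                    pos1, score = int(fields[0]), float(fields[1])
                    track.set_range(chrom, pos1 - 1, pos1 - 1 + span, score)
                else:
                    if len(fields) < 4:
                        raise ValueError("bedGraph needs 4 columns")
                    track.set_range(fields[0], int(fields[1]), int(fields[2]),
                                    float(fields[3]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return track


def read_expression(path, normal_ids: Optional[Sequence[str]] = None) -> ExpressionMatrix:
    """Read a gene-by-sample expression TSV (header = sample IDs, first
    column = gene symbols); ``NA`` / empty cells become missing values."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    return ExpressionMatrix(df, normal_ids or ())


def read_genome(path) -> dict[str, str]:
    """Load a FASTA genome into a chrom -> uppercase sequence mapping."""
    from Bio import SeqIO

    return {normalize_chrom(rec.id): str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


# Output table, mirroring the published annotation column order:
# position block, gene block, expression block, chromatin flags,
# conservation, motif changes, promoter/enhancer transcription flags.
ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "sample", "gene", "distance_to_tss",
    "fold_change", "p_value", "adj_p_value",
    "dhs", "h3k4me1", "h3k4me3", "h3k27ac",
    "conservation", "background_conservation",
    "motifs_created", "motifs_removed",
    "fantom_promoter", "fantom_enhancer",
]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return format(value, ".6g")
    return str(value)


def write_annotations(records: Iterable[AnnotationRecord], path) -> None:
    """Write annotation records as TSV; flags 0/1, missing fields empty,
    motif lists semicolon-joined and sorted."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for rec in records:
            m = rec.mutation
            row = [
                m.chrom, str(m.pos), m.ref or "-", m.alt or "-", m.sample_id,
                _fmt(rec.gene), _fmt(rec.distance_to_tss),
                _fmt(rec.fold_change), _fmt(rec.p_value), _fmt(rec.adj_p_value),
                _fmt(rec.in_dhs), _fmt(rec.h3k4me1), _fmt(rec.h3k4me3),
                _fmt(rec.h3k27ac),
                _fmt(rec.conservation), _fmt(rec.background_conservation),
                ";".join(sorted(rec.motifs_created)),
                ";".join(sorted(rec.motifs_removed)),
                _fmt(rec.fantom_promoter), _fmt(rec.fantom_enhancer),
            ]
            fh.write("\t".join(row) + "\n")


def _parse_opt(s: str, cast):
    return None if s == "" else cast(s)


def read_annotations(path) -> list[AnnotationRecord]:
    """Read back a TSV produced by :func:`write_annotations`."""
    path = Path(path)
    records: list[AnnotationRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ANNOTATION_COLUMNS:
            raise ValueError(f"{path}: unexpected annotation header")
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            f = dict(zip(ANNOTATION_COLUMNS, raw.rstrip("\n").split("\t")))
            mut = Mutation(f["chrom"], int(f["pos"]),
                           "" if f["ref"] == "-" else f["ref"],
                           "" if f["alt"] == "-" else f["alt"], f["sample"])
            records.append(AnnotationRecord(
                mutation=mut,
                gene=f["gene"] or None,
                distance_to_tss=_parse_opt(f["distance_to_tss"], int),
                in_dhs=f["dhs"] == "1",
                h3k4me1=f["h3k4me1"] == "1",
                h3k4me3=f["h3k4me3"] == "1",
                h3k27ac=f["h3k27ac"] == "1",
                conservation=_parse_opt(f["conservation"], float),
                background_conservation=_parse_opt(f["background_conservation"], float),
                motifs_created=frozenset(x for x in f["motifs_created"].split(";") if x),
                motifs_removed=frozenset(x for x in f["motifs_removed"].split(";") if x),
                fantom_promoter=f["fantom_promoter"] == "1",
                fantom_enhancer=f["fantom_enhancer"] == "1",
                fold_change=_parse_opt(f["fold_change"], float),
                p_value=_parse_opt(f["p_value"], float),
                adj_p_value=_parse_opt(f["adj_p_value"], float),
            ))
    return records
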