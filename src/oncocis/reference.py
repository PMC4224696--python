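"""Bundled published annotation tables, used as worked examples and as
desk-scale checks of the distance convention and the prioritization
filter.

Two tables ship with the package:

* the two recurrent TERT promoter mutations with their full annotation
  (the classic validation case: both create an ETS factor binding site
  -66 and -88 bp upstream of the TERT TSS);
* the 18 prioritized candidate cis-regulatory mutations from 17
  whole-genome breast cancers (HMEC chromatin context).

The published breast-cancer table does not print ref/alt alleles (except
for the experimentally validated CDK6 G>C record); a placeholder
substitution is used so the rows can be carried by the standard
Mutation container — no analysis here depends on the alleles.
"""

from __future__ import annotations

import csv
from importlib import resources
from typing import Optional

from .core import AnnotationRecord, GeneModel, Mutation

__all__ = ["load_tert_annotations", "load_breast_prioritized",
           "tert_gene_model", "TERT_TSS"]

# Derived from one printed mutation-distance pair (chr5:1,295,228 at -66
# on the minus strand): tss = pos + distance.
TERT_TSS = 1_295_228 - 66


def tert_gene_model() -> GeneModel:
    return GeneModel("TERT", "chr5", TERT_TSS, "-")


def _rows(filename: str):
    path = resources.files("oncocis.data").joinpath(filename)
    with path.open() as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    return list(csv.DictReader(lines, delimiter="\t"))


def _placeholder_alleles(ref: str, alt: str) -> tuple[str, str]:
    if ref and alt:
        return ref, alt
    return "N", "A"


def _record(row: dict) -> AnnotationRecord:
    ref, alt = _placeholder_alleles(row.get("ref", ""), row.get("alt", ""))
    mut = Mutation(row["chrom"], int(row["pos"]), ref, alt, row["sample"])
    def flag(k): return row[k] == "1"
    def opt_float(k) -> Optional[float]:
        v = row.get(k, "")
        return float(v) if v not in ("", None) else None
    return AnnotationRecord(
        mutation=mut,
        gene=row["gene"],
        distance_to_tss=int(row["distance_to_tss"]),
        in_dhs=flag("dhs"),
        h3k4me1=flag("h3k4me1"), h3k4me3=flag("h3k4me3"), h3k27ac=flag("h3k27ac"),
        conservation=opt_float("conservation"),
        motifs_created=frozenset(x for x in row["created"].split(";") if x),
        motifs_removed=frozenset(x for x in row["removed"].split(";") if x),
        fantom_promoter=flag("fantom_promoter"),
        fantom_enhancer=flag("fantom_enhancer"),
        fold_change=opt_float("fold_change"),
        adj_p_value=opt_float("adj_p_value"),
    )


def load_tert_annotations() -> list[AnnotationRecord]:
    """The two annotated TERT promoter mutations."""
    return [_record(r) for r in _rows("tert_promoter_annotations.tsv")]


def load_breast_prioritized() -> list[AnnotationRecord]:
    """The 18 prioritized breast-cancer records."""
    return [_record(r) for r in _rows("breast_prioritized_annotations.tsv")]
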