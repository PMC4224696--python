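"""Domain types, coordinate conventions, and file readers/writers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncocis import (AnnotationRecord, GenomicInterval, Mutation,
                     MutationKind, PeakSet)
from oncocis import io as ocio


class TestMutation:
    @pytest.mark.parametrize("ref,alt,kind", [
        ("G", "A", MutationKind.SUBSTITUTION),
        ("GT", "CA", MutationKind.SUBSTITUTION),
        ("", "TT", MutationKind.INSERTION),
        ("TG", "", MutationKind.DELETION),
    ])
    def test_kind_derived_from_allele_lengths(self, ref, alt, kind):
        assert Mutation("chr1", 100, ref, alt, "S1").kind is kind

    def test_shared_prefix_trimmed_with_anchor_advance(self):
        m = Mutation.from_alleles("chr1", 100, "AT", "A", "S1")
        assert (m.pos, m.ref, m.alt, m.kind) == (101, "T", "", MutationKind.DELETION)

    def test_insertion_anchored_after_shared_base(self):
        m = Mutation.from_alleles("chr1", 100, "A", "AT", "S1")
        assert (m.pos, m.ref, m.alt, m.kind) == (100, "", "T", MutationKind.INSERTION)

    def test_invalid_mutations_rejected(self):
        with pytest.raises(ValueError):
            Mutation("chr1", 0, "G", "A", "S1")
        with pytest.raises(ValueError):
            Mutation("chr1", 5, "G", "G", "S1")

    def test_chrom_prefix_added_never_stripped(self):
        assert Mutation("5", 10, "G", "A", "S1").chrom == "chr5"
        assert Mutation("chr5", 10, "G", "A", "S1").chrom == "chr5"


class TestBedSemantics:
    def test_half_open_boundaries(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t10\t20\n")
        peaks = ocio.read_bed(bed, "DHS")
        assert not peaks.query_point("chr1", 10)  # base before the interval
        assert peaks.query_point("chr1", 11)      # first covered base
        assert peaks.query_point("chr1", 20)      # last covered base
        assert not peaks.query_point("chr1", 21)

    def test_invalid_interval_reports_line(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t5\t9\nchr1\t30\t20\n")
        with pytest.raises(ValueError, match=":2"):
            ocio.read_bed(bed)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 60)),
                    min_size=1, max_size=60),
           st.integers(1, 600), st.randoms(use_true_random=False))
    def test_point_queries_match_linear_scan_and_order(self, ivs, pos1, rnd):
        intervals = [GenomicInterval("chr1", s, s + w) for s, w in ivs]
        expected = sorted((iv for iv in intervals if iv.start < pos1 <= iv.end),
                          key=lambda iv: (iv.start, iv.end))
        shuffled = list(intervals)
        rnd.shuffle(shuffled)
        for order in (intervals, shuffled):
            assert PeakSet("other", order).query_point("chr1", pos1) == expected


class TestReaders:
    def test_mutation_tsv(self, tmp_path):
        f = tmp_path / "m.tsv"
        f.write_text("chr5\t1295228\tG\tA\tS1\n1\t100\tAT\tA\tS1\n")
        muts = ocio.read_mutations(f)
        assert muts[0] == Mutation("chr5", 1295228, "G", "A", "S1")
        assert (muts[1].pos, muts[1].kind) == (101, MutationKind.DELETION)

    def test_mutation_tsv_errors_name_line(self, tmp_path):
        f = tmp_path / "m.tsv"
        f.write_text("chr1\t100\tG\tA\tS1\nchr1\txx\tG\tA\tS1\n")
        with pytest.raises(ValueError, match=":2"):
            ocio.read_mutations(f)
        f.write_text("chr1\t100\tG\tA\n")
        with pytest.raises(ValueError, match="5 columns"):
            ocio.read_mutations(f)

    def test_empty_mutation_file_warns(self, tmp_path, caplog):
        f = tmp_path / "m.tsv"
        f.write_text("")
        assert ocio.read_mutations(f) == []
        assert any("no mutations" in r.message for r in caplog.records)

    def test_vcf_multi_alt_expansion(self, tmp_path):
        f = tmp_path / "m.vcf"
        f.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="sample">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\t.\tG\tA,C\t.\t.\tSAMPLE=S7\n")
        muts = ocio.read_mutations(f, dialect="vcf")
        assert [(m.alt, m.sample_id) for m in muts] == [("A", "S7"), ("C", "S7")]

    def test_pfm_reader(self, tmp_path):
        f = tmp_path / "m.pfm"
        f.write_text(">MA0001.1 TF1 taxon=mammals\n"
                     "A [ 8 0 2 ]\nC [ 0 8 2 ]\nG [ 2 2 4 ]\nT [ 0 0 2 ]\n"
                     ">MA0002.1 TF2\n1 2\n3 0\n0 1\n0 1\n")
        motifs = ocio.read_pfm(f)
        assert [m.name for m in motifs] == ["TF1", "TF2"]
        assert motifs[0].width == 3 and motifs[0].n_sites == 10
        assert motifs[0].taxon == "mammals" and motifs[1].taxon == "unknown"

    @pytest.mark.parametrize("body", [
        "A [ 1 x ]\nC [ 0 1 ]\nG [ 0 0 ]\nT [ 1 0 ]",   # non-numeric
        "A [ 1 1 ]\nC [ 0 ]\nG [ 0 0 ]\nT [ 1 0 ]",     # unequal width
        "A [ -1 1 ]\nC [ 0 1 ]\nG [ 0 0 ]\nT [ 1 0 ]",  # negative count
    ])
    def test_pfm_rejects_malformed(self, tmp_path, body):
        f = tmp_path / "bad.pfm"
        f.write_text(">M X taxon=mammals\n" + body + "\n")
        with pytest.raises(ValueError):
            ocio.read_pfm(f)

    def test_bedgraph_conservation(self, tmp_path):
        f = tmp_path / "c.bedGraph"
        f.write_text("chr1\t0\t2\t0.5\nchr1\t4\t5\t0.9\n")
        track = ocio.read_conservation(f)
        assert track.get("chr1", 1) == 0.5 and track.get("chr1", 2) == 0.5
        assert track.get("chr1", 3) is None
        assert track.get("chr1", 5) == 0.9

    def test_wiggle_dialects(self, tmp_path):
        f = tmp_path / "c.wig"
        f.write_text("fixedStep chrom=chr1 start=10 step=1\n0.1\n0.2\n"
                     "variableStep chrom=chr2\n7 0.8\n")
        track = ocio.read_conservation(f)
        assert track.get("chr1", 10) == pytest.approx(0.1)
        assert track.get("chr1", 11) == pytest.approx(0.2)
        assert track.get("chr2", 7) == pytest.approx(0.8)

    def test_conservation_rejects_bad_tracks(self, tmp_path):
        f = tmp_path / "c.bedGraph"
        f.write_text("chr1\t0\t2\t1.5\n")
        with pytest.raises(ValueError, match="outside"):
            ocio.read_conservation(f)
        f.write_text("chr1\t0\t2\t0.5\nchr1\t1\t3\t0.4\n")
        with pytest.raises(ValueError, match="overlapping"):
            ocio.read_conservation(f)

    def test_expression_reader(self, tmp_path):
        f = tmp_path / "e.tsv"
        f.write_text("gene\tS1\tS2\tN1\nG1\t1.0\t2.0\t3.0\nG2\tNA\t5.0\t6.0\n")
        expr = ocio.read_expression(f, normal_ids=["N1"])
        assert expr.get("G1", "S2") == 2.0
        assert expr.get("G2", "S1") is None  # NA cell -> missing
        assert expr.normal_samples == {"N1"}
        with pytest.raises(ValueError, match="absent"):
            ocio.read_expression(f, normal_ids=["NX"])


class TestAnnotationRoundTrip:
    def test_write_read_identity(self, tmp_path):
        rec = AnnotationRecord(
            mutation=Mutation("chr5", 1295228, "G", "A", "S1"),
            gene="TERT", distance_to_tss=-66, in_dhs=True, h3k4me3=True,
            conservation=0.008, background_conservation=0.1,
            motifs_created=frozenset({"ELK1", "ELF1"}),
            motifs_removed=frozenset({"TFAP2A"}),
            fantom_promoter=True, fold_change=2.5, p_value=0.001,
            adj_p_value=0.01)
        bare = AnnotationRecord(mutation=Mutation("chr2", 7, "", "TA", "S2"))
        out = tmp_path / "ann.tsv"
        ocio.write_annotations([rec, bare], out)
        back = ocio.read_annotations(out)
        assert len(back) == 2
        for orig, rt in zip([rec, bare], back):
            for f in ("gene", "distance_to_tss", "in_dhs", "h3k4me1", "h3k4me3",
                      "h3k27ac", "motifs_created", "motifs_removed",
                      "fantom_promoter", "fantom_enhancer"):
                assert getattr(rt, f) == getattr(orig, f)
            assert rt.mutation == orig.mutation
            for f in ("conservation", "fold_change", "p_value", "adj_p_value"):
                o = getattr(orig, f)
                assert getattr(rt, f) == (pytest.approx(o) if o is not None else None)

    def test_empty_record_set_gives_header_only(self, tmp_path):
        out = tmp_path / "ann.tsv"
        ocio.write_annotations([], out)
        assert out.read_text().count("\n") == 1
        assert ocio.read_annotations(out) == []


class TestAnnotationInvariants:
    def test_created_and_removed_disjoint(self):
        with pytest.raises(ValueError):
            AnnotationRecord(mutation=Mutation("chr1", 5, "G", "A", "S"),
                             motifs_created={"A"}, motifs_removed={"A"})

    def test_insertion_carries_no_conservation(self):
        with pytest.raises(ValueError):
            AnnotationRecord(mutation=Mutation("chr1", 5, "", "T", "S"),
                             conservation=0.5)
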