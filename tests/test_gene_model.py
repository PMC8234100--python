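"""Gene-model construction, parsing, and region derivation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splicedex import intervals as iv
from splicedex.gene_model import (
    CoordinateError,
    GeneModel,
    GeneModelError,
    TranscriptExon,
    constitutive_regions,
    corresponding_genomic_exon,
    intergenic_regions,
    parse_annotation,
    write_gtf,
)
from splicedex.synthetic_data import make_toy_annotation, toy_chrom_sizes


def _gtf_line(chrom, start, end, strand, gid, tid):
    return (f'{chrom}\tsrc\texon\t{start}\t{end}\t.\t{strand}\t.\t'
            f'gene_id "{gid}"; transcript_id "{tid}";\n')


class TestParseAnnotation:
    def test_single_transcript_gene(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text("".join(
            _gtf_line("chr1", s, e, "+", "G", "T")
            for s, e in [(100, 200), (300, 400), (500, 600)]
        ))
        models = parse_annotation(str(p))
        m = models["G"]
        assert [g.exon_label for g in m.genomic_exons] == ["e1", "e2", "e3"]
        assert [te.role for te in m.transcripts["T"]] == ["first", "internal", "last"]

    def test_minus_strand_labels_right_to_left(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text("".join(
            _gtf_line("chr1", s, e, "-", "G", "T")
            for s, e in [(100, 200), (300, 400), (500, 600)]
        ))
        m = parse_annotation(str(p))["G"]
        assert [(g.exon_label, g.start) for g in m.genomic_exons] == [
            ("e1", 500), ("e2", 300), ("e3", 100)
        ]
        # transcript chain also runs right to left
        assert m.transcripts["T"][0].start == 500
        assert m.transcripts["T"][0].role == "first"

    def test_two_transcript_membership(self, tmp_path):
        p = tmp_path / "g.gtf"
        lines = [_gtf_line("chr1", s, e, "+", "G", "tA")
                 for s, e in [(100, 200), (300, 400), (500, 600)]]
        lines += [_gtf_line("chr1", s, e, "+", "G", "tB")
                  for s, e in [(100, 200), (500, 600)]]
        p.write_text("".join(lines))
        m = parse_annotation(str(p))["G"]
        assert len(m.genomic_exons) == 3
        e2 = m.exon_by_label("e2")
        covers = {
            tid: any(iv.overlap_len((te.start, te.end), (e2.start, e2.end)) > 0
                     for te in tes)
            for tid, tes in m.transcripts.items()
        }
        assert covers == {"tA": True, "tB": False}

    def test_transcript_on_two_strands_rejected(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text(
            _gtf_line("chr1", 100, 200, "+", "G", "T")
            + _gtf_line("chr1", 300, 400, "-", "G", "T")
        )
        with pytest.raises(GeneModelError, match="T"):
            parse_annotation(str(p))

    def test_round_trip(self, tmp_path, toy_models):
        out = tmp_path / "rt.gtf"
        write_gtf(toy_models, str(out))
        reparsed = parse_annotation(str(out))
        assert set(reparsed) == set(toy_models)
        for gid, m in toy_models.items():
            assert reparsed[gid].genomic_exons == m.genomic_exons
            assert reparsed[gid].transcripts == m.transcripts


class TestCorrespondingExon:
    @pytest.fixture()
    def model(self):
        return GeneModel.from_transcript_exons(
            "G", "chr1", "+",
            {"tA": [(100, 200), (300, 400), (500, 600)]},
        )

    def test_identity(self, model):
        te = model.transcripts["tA"][1]
        assert corresponding_genomic_exon(te, model).exon_label == "e2"

    def test_maximal_overlap_wins(self, model):
        # overlaps e2 by 40 nt and e3 by 5 nt
        te = TranscriptExon("tX", 1, "chr1", 361, 504, "+", "only")
        assert corresponding_genomic_exon(te, model).exon_label == "e2"

    def test_intronic_exon_has_no_correspondence(self, model):
        te = TranscriptExon("tX", 1, "chr1", 210, 290, "+", "only")
        assert corresponding_genomic_exon(te, model) is None


class TestConstitutiveRegions:
    def test_single_transcript_verbatim(self):
        m = GeneModel.from_transcript_exons("G", "chr1", "+",
                                            {"t": [(100, 200), (300, 400)]})
        assert [(r.start, r.end) for r in constitutive_regions(m)] == [
            (100, 200), (300, 400)
        ]

    def test_shared_exon_only(self):
        m = GeneModel.from_transcript_exons(
            "G", "chr1", "+",
            {"tA": [(100, 200), (300, 400)], "tB": [(100, 200), (500, 600)]},
        )
        assert [(r.start, r.end) for r in constitutive_regions(m)] == [(100, 200)]

    def test_partial_overlap_intersection(self):
        m = GeneModel.from_transcript_exons(
            "G", "chr1", "+", {"tA": [(100, 200)], "tB": [(150, 250)]}
        )
        assert [(r.start, r.end) for r in constitutive_regions(m)] == [(150, 200)]

    def test_subset_of_every_transcript(self, toy_models):
        for m in toy_models.values():
            const = [(r.start, r.end) for r in constitutive_regions(m)]
            for tes in m.transcripts.values():
                footprint = [(te.start, te.end) for te in tes]
                assert iv.intersect(const, footprint) == iv.merge(const)


class TestIntergenicRegions:
    def test_complement_of_one_gene(self):
        m = GeneModel.from_transcript_exons("G", "c", "+", {"t": [(1000, 2000)]})
        regions = intergenic_regions([m], {"c": 10000})
        assert [(r.start, r.end) for r in regions] == [(1, 999), (2001, 10000)]

    def test_gene_covering_chromosome(self):
        m = GeneModel.from_transcript_exons("G", "c", "+", {"t": [(1, 500)]})
        assert intergenic_regions([m], {"c": 500}) == []

    def test_overlapping_genes_merged(self):
        a = GeneModel.from_transcript_exons("A", "c", "+", {"t": [(100, 300)]})
        b = GeneModel.from_transcript_exons("B", "c", "+", {"t": [(200, 400)]})
        regions = intergenic_regions([a, b], {"c": 1000})
        assert [(r.start, r.end) for r in regions] == [(1, 99), (401, 1000)]

    def test_span_exceeding_chromosome_rejected(self):
        m = GeneModel.from_transcript_exons("G", "c", "+", {"t": [(100, 900)]})
        with pytest.raises(CoordinateError):
            intergenic_regions([m], {"c": 500})

    def test_tiles_chromosome_with_gene_spans(self, toy_models):
        sizes = toy_chrom_sizes()
        inter = [(r.start, r.end) for r in intergenic_regions(toy_models, sizes)]
        spans = [m.span for m in toy_models.values()]
        chrom_size = sizes["chrS"]
        assert iv.merge(inter + spans) == [(1, chrom_size)]
        for s in spans:
            assert iv.intersect(inter, [s]) == []


@settings(max_examples=25, deadline=None)
@given(offset=st.integers(min_value=-50, max_value=10_000))
def test_labels_invariant_under_translation(offset):
    """Shifting a whole gene leaves exon/intron labels unchanged."""
    base = {"tA": [(101, 200), (301, 400), (501, 600)], "tB": [(101, 200), (501, 600)]}
    shifted = {t: [(s + offset, e + offset) for s, e in ex] for t, ex in base.items()}
    m0 = GeneModel.from_transcript_exons("G", "c", "+", base)
    m1 = GeneModel.from_transcript_exons("G", "c", "+", shifted)
    assert [g.exon_label for g in m0.genomic_exons] == [
        g.exon_label for g in m1.genomic_exons
    ]
    assert [lab for lab, *_ in m0.introns()] == [lab for lab, *_ in m1.introns()]
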