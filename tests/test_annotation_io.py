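import pytest

from chimeraudit import annotation_io as aio
from chimeraudit.annotation_io import GenomeSequence, ProteinRecord
from chimeraudit.errors import (
    FastaError,
    FrameError,
    Gff3ParseError,
    Gff3StructuralError,
)

SIMPLE_GFF = """
chr1 . gene 101 200 . + . ID=g1
chr1 . mRNA 101 200 . + . ID=t1;Parent=g1
chr1 . CDS 101 190 . + 0 ID=c1;Parent=t1
"""


class TestParseGff3:
    def test_coordinates_converted_to_half_open(self, gff_file):
        ann = aio.parse_gff3(gff_file(SIMPLE_GFF))
        g = ann["g1"]
        assert (g.start, g.end) == (100, 200)
        assert g.strand == "+"
        assert g.transcripts[0].cds_segments == [(100, 190, 0)]

    def test_counts_genes_and_transcripts(self, gff_file):
        text = """
        chr1 . gene 1 1000 . + . ID=g1
        chr1 . mRNA 1 1000 . + . ID=t1;Parent=g1
        chr1 . CDS 1 300 . + 0 ID=c1;Parent=t1
        chr1 . CDS 401 700 . + 0 ID=c2;Parent=t1
        chr1 . mRNA 1 500 . + . ID=t2;Parent=g1
        chr1 . CDS 1 300 . + 0 ID=c3;Parent=t2
        """
        ann = aio.parse_gff3(gff_file(text))
        assert len(ann) == 1
        assert ann.n_transcripts == 2
        assert len(ann["g1"].transcripts[0].cds_segments) == 2

    def test_orphan_cds_is_structural_error(self, gff_file):
        text = SIMPLE_GFF + "chr1 . CDS 300 400 . + 0 ID=c9;Parent=missing\n"
        with pytest.raises(Gff3StructuralError, match="missing"):
            aio.parse_gff3(gff_file(text))

    def test_malformed_line_names_line_number(self, gff_file, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("##gff-version 3\nchr1\tonly-two-cols\n")
        with pytest.raises(Gff3ParseError, match=":2"):
            aio.parse_gff3(path)

    def test_unknown_strand_rejected(self, gff_file):
        text = """
        chr1 . gene 101 200 . . . ID=g1
        chr1 . mRNA 101 200 . . . ID=t1;Parent=g1
        chr1 . CDS 101 190 . . 0 ID=c1;Parent=t1
        """
        with pytest.raises(Gff3StructuralError, match="strand"):
            aio.parse_gff3(gff_file(text))

    def test_round_trip_preserves_coordinates(self, bundle, tmp_path):
        path = tmp_path / "rt.gff3"
        aio.write_gff3(bundle.reference, path)
        reread = aio.parse_gff3(path)
        assert sorted(reread.gene_ids) == sorted(bundle.reference.gene_ids)
        for g in bundle.reference:
            r = reread[g.gene_id]
            assert (r.start, r.end, r.strand, r.seq_id) == (g.start, g.end, g.strand, g.seq_id)
            assert [t.cds_segments for t in r.transcripts] == [
                t.cds_segments for t in g.transcripts
            ]


class TestSelectLongestIsoform:
    TWO_ISOFORMS = """
    chr1 . gene 1 2000 . + . ID=g1
    chr1 . mRNA 1 2000 . + . ID=tshort;Parent=g1
    chr1 . CDS 1 750 . + 0 ID=c1;Parent=tshort
    chr1 . mRNA 1 2000 . + . ID=tlong;Parent=g1
    chr1 . CDS 1 1200 . + 0 ID=c2;Parent=tlong
    """

    def test_keeps_longest_protein(self, gff_file):
        ann = aio.select_longest_isoform(aio.parse_gff3(gff_file(self.TWO_ISOFORMS)))
        assert [t.transcript_id for t in ann["g1"].transcripts] == ["tlong"]

    def test_tie_broken_by_lexicographic_id(self, gff_file):
        text = """
        chr1 . gene 1 900 . + . ID=g1
        chr1 . mRNA 1 900 . + . ID=tB;Parent=g1
        chr1 . CDS 1 900 . + 0 ID=c1;Parent=tB
        chr1 . mRNA 1 900 . + . ID=tA;Parent=g1
        chr1 . CDS 1 900 . + 0 ID=c2;Parent=tA
        """
        ann = aio.select_longest_isoform(aio.parse_gff3(gff_file(text)))
        assert ann["g1"].transcripts[0].transcript_id == "tA"

    def test_single_isoform_unchanged_and_idempotent(self, gff_file):
        once = aio.select_longest_isoform(aio.parse_gff3(gff_file(SIMPLE_GFF)))
        twice = aio.select_longest_isoform(once)
        assert [t.transcript_id for g in twice for t in g.transcripts] == ["t1"]

    def test_noncoding_gene_dropped(self, gff_file):
        text = """
        chr1 . gene 1 500 . + . ID=g1
        chr1 . mRNA 1 500 . + . ID=t1;Parent=g1
        """
        ann = aio.select_longest_isoform(aio.parse_gff3(gff_file(text)))
        assert len(ann) == 0


def _single_gene(seq, cds, strand, phase=0):
    from chimeraudit.annotation_io import GeneModel, TranscriptModel

    tm = TranscriptModel(transcript_id="t1", cds_segments=[(s, e, p) for s, e, p in cds])
    return (
        GeneModel(gene_id="g1", seq_id="s1", strand=strand, start=0, end=len(seq), transcripts=[tm]),
        GenomeSequence(seq_id="s1", residues=seq),
    )


class TestExtractProtein:
    def test_plus_strand_stop_trimmed(self):
        gene, genome = _single_gene("ATGAAATAG", [(0, 9, 0)], "+")
        assert aio.extract_protein(gene, genome).sequence == "MK"

    def test_minus_strand_is_reverse_complement(self):
        gene, genome = _single_gene("CTATTTCAT", [(0, 9, 0)], "-")
        assert aio.extract_protein(gene, genome).sequence == "MK"

    def test_minus_strand_matches_explicit_revcomp(self, bundle):
        # translating a '-' gene equals translating its reverse complement
        # re-laid on the plus strand
        for gene in bundle.reference:
            if gene.strand != "-":
                continue
            rec = aio.extract_protein(gene, bundle.genome[gene.seq_id])
            segs = gene.transcripts[0].cds_segments
            cds = "".join(bundle.genome[gene.seq_id].residues[s:e] for s, e, _ in segs)
            flipped = aio.reverse_complement(cds)
            plus_gene, plus_genome = _single_gene(flipped, [(0, len(flipped), 0)], "+")
            assert aio.extract_protein(plus_gene, plus_genome).sequence == rec.sequence
            break
        else:
            pytest.fail("bundle contained no minus-strand gene")

    def test_frame_error_on_non_codon_multiple(self):
        gene, genome = _single_gene("ATGAAATA", [(0, 8, 0)], "+")
        with pytest.raises(FrameError, match="t1"):
            aio.extract_protein(gene, genome)

    def test_phase_trims_leading_bases(self):
        gene, genome = _single_gene("CCATGAAATAG", [(0, 11, 2)], "+")
        assert aio.extract_protein(gene, genome).sequence == "MK"

    def test_ambiguous_codon_translates_to_x(self):
        gene, genome = _single_gene("ATGAANTAG", [(0, 9, 0)], "+")
        assert aio.extract_protein(gene, genome).sequence == "MX"

    def test_internal_stop_flagged_and_retained(self):
        gene, genome = _single_gene("ATGTAAAAATAG", [(0, 12, 0)], "+")
        rec = aio.extract_protein(gene, genome)
        assert rec.sequence == "M*K"
        assert rec.internal_stop

    def test_cds_outside_genome_rejected(self):
        gene, genome = _single_gene("ATGAAATAG", [(0, 12, 0)], "+")
        with pytest.raises(Gff3StructuralError):
            aio.extract_protein(gene, genome)

    def test_cds_length_bounds_protein_length(self, bundle):
        # protein_len*3 <= total CDS <= protein_len*3 + 3 (stop accounting)
        for gene in bundle.reference:
            rec = aio.extract_protein(gene, bundle.genome[gene.seq_id])
            total = gene.transcripts[0].total_cds_length
            assert rec.length * 3 <= total <= rec.length * 3 + 3


class TestProteinFasta:
    def test_write_and_reread(self, tmp_path):
        recs = [
            ProteinRecord("p1", "M" + "A" * 70, gene_id="g1"),
            ProteinRecord("p2", "MKV", gene_id="g2"),
        ]
        path = tmp_path / "p.fasta"
        aio.write_protein_fasta(recs, path)
        text = path.read_text()
        assert text.count(">") == 2
        assert ">p1 gene_id=g1 length=71" in text
        assert max(len(l) for l in text.splitlines()) <= 71  # 60-col wrap
        reread = aio.read_protein_fasta(path)
        assert [r.sequence for r in reread] == [r.sequence for r in recs]

    def test_empty_list_writes_empty_file(self, tmp_path):
        path = tmp_path / "e.fasta"
        aio.write_protein_fasta([], path)
        assert path.read_text() == ""

    @pytest.mark.parametrize(
        "records",
        [
            [ProteinRecord("p1", "MK"), ProteinRecord("p1", "MV")],  # duplicate ID
            [ProteinRecord("p1", "")],  # zero length
        ],
    )
    def test_invalid_records_rejected_before_writing(self, tmp_path, records):
        path = tmp_path / "bad.fasta"
        with pytest.raises(FastaError):
            aio.write_protein_fasta(records, path)
        assert not path.exists()
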