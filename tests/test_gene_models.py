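"""Gene-model parsing, splice classification, translation, intron phases."""

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from splicetrace.errors import (
    DegenerateIntronError,
    ParseError,
    PartialModelError,
    PseudogeneError,
    UnknownReferenceError,
)
from splicetrace.gene_models import (
    ExonInterval,
    GeneModel,
    GenomicSequence,
    classify_splice_sites,
    intron_positions,
    parse_gene_models,
    spliced_protein,
)
from conftest import build_gene


def write_exon_table(tmp_path, rows):
    path = tmp_path / "models.tsv"
    header = "gene_id\ttaxon\tgenome_id\tstrand\texon_start\texon_end\trank\n"
    path.write_text(header + "".join("\t".join(map(str, r)) + "\n" for r in rows))
    return path


class TestParseGeneModels:
    def test_single_exon_record(self, tmp_path):
        genome = GenomicSequence(id="G", residues="ATGGCTTAA" + "C" * 20)
        path = write_exon_table(tmp_path, [("g1", "tax", "G", "+", 0, 9, 1)])
        (model,) = parse_gene_models(path, {"G": genome})
        assert len(model.exons) == 1 and model.n_introns == 0
        assert not model.partial_flag

    def test_two_exons_hand_parsed(self, tmp_path):
        model0, genome = build_gene("ATGGCTGCTTAA", [6])
        rows = [("g1", "taxonA", genome.id, "+", e.start, e.end, e.rank)
                for e in model0.exons]
        path = write_exon_table(tmp_path, rows)
        (model,) = parse_gene_models(path, {genome.id: genome})
        assert [(e.start, e.end, e.rank) for e in model.exons] == \
            [(e.start, e.end, e.rank) for e in model0.exons]

    def test_minus_strand_out_of_genomic_order(self, tmp_path):
        """Rows listed in transcript order on '-' descend in genomic coords."""
        model0, genome = build_gene("ATGGCTGCTTAA", [6], strand="-")
        rows = [("g1", "taxonA", genome.id, "-", e.start, e.end, e.rank)
                for e in model0.exons]
        path = write_exon_table(tmp_path, rows)
        (model,) = parse_gene_models(path, {genome.id: genome})
        assert spliced_protein(model, genome).residues == "MAA"

    def test_malformed_interval(self, tmp_path):
        genome = GenomicSequence(id="G", residues="ATGGCTTAA")
        path = write_exon_table(tmp_path, [("g1", "t", "G", "+", 9, 0, 1)])
        with pytest.raises(ParseError):
            parse_gene_models(path, {"G": genome})

    def test_unknown_genome(self, tmp_path):
        path = write_exon_table(tmp_path, [("g1", "t", "NOPE", "+", 0, 9, 1)])
        with pytest.raises(UnknownReferenceError):
            parse_gene_models(path, {})

    def test_incomplete_cds_flagged_partial(self, tmp_path):
        genome = GenomicSequence(id="G", residues="CCCGCTGCTGCT")
        path = write_exon_table(tmp_path, [("g1", "t", "G", "+", 0, 12, 1)])
        (model,) = parse_gene_models(path, {"G": genome})
        assert model.partial_flag

    def test_gff3_input(self, tmp_path):
        genome = GenomicSequence(id="chr1", residues="ATGGCT" + "GTATCGAG" + "GCTTAA")
        gff = tmp_path / "m.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\t.\texon\t1\t6\t.\t+\t.\tgene_id=g1;rank=1\n"
            "chr1\t.\texon\t15\t20\t.\t+\t.\tgene_id=g1;rank=2\n"
        )
        (model,) = parse_gene_models(gff, {"chr1": genome})
        assert spliced_protein(model, genome).residues == "MAA"
        assert classify_splice_sites(model, genome)[0].klass == "canonical"


class TestSpliceSites:
    @pytest.mark.parametrize("intron,expect", [
        ("GTAAGCTTCAG", ("GT", "AG", "canonical")),
        ("GCAAGCTTCAG", ("GC", "AG", "noncanonical")),
        ("ATAAGCTTTAC", ("AT", "AC", "other")),
    ])
    def test_dinucleotide_classes(self, intron, expect):
        model, genome = build_gene("ATGGCTGCTTAA", [6], intron_seq=intron)
        (chk,) = classify_splice_sites(model, genome)
        assert (chk.donor, chk.acceptor, chk.klass) == expect

    def test_n_in_dinucleotide_warns_not_crashes(self):
        model, genome = build_gene("ATGGCTGCTTAA", [6], intron_seq="GNAAGCTTCAG")
        with pytest.warns(UserWarning):
            (chk,) = classify_splice_sites(model, genome)
        assert chk.klass == "other"

    def test_degenerate_intron(self):
        model, genome = build_gene("ATGGCTGCTTAA", [6], intron_seq="GTA")
        with pytest.raises(DegenerateIntronError):
            classify_splice_sites(model, genome)

    def test_strand_symmetry(self):
        """The same transcript built on either strand gives identical checks."""
        for intron in ("GTAAGCTTCAG", "GCAAGCTTCAG"):
            plus, gplus = build_gene("ATGGCTGCTTAA", [6], intron_seq=intron)
            minus, gminus = build_gene("ATGGCTGCTTAA", [6], strand="-",
                                       intron_seq=intron)
            assert classify_splice_sites(plus, gplus) == \
                classify_splice_sites(minus, gminus)


class TestSplicedProtein:
    def test_start_ala_stop(self):
        model, genome = build_gene("ATGGCTTAA", [])
        assert spliced_protein(model, genome).residues == "MA"

    def test_minus_strand_translation(self):
        """Oracle: independent codon-table translation of the revcomp CDS."""
        model, genome = build_gene("ATGTGGTGA", [], strand="-")
        table = {"ATG": "M", "TGG": "W"}
        expected = "".join(table[c] for c in ("ATG", "TGG"))
        assert spliced_protein(model, genome).residues == expected == "MW"

    def test_internal_stop_is_pseudogene(self):
        model, genome = build_gene("ATGTAAGCTTGA", [])
        with pytest.raises(PseudogeneError):
            spliced_protein(model, genome)

    def test_partial_model_refused(self):
        model, genome = build_gene("ATGGCTTAA", [])
        model.partial_flag = True
        with pytest.raises(PartialModelError):
            spliced_protein(model, genome)


class TestIntronPositions:
    @pytest.mark.parametrize("lengths,expected", [
        ((9, 9), [(1, 4, 0)]),
        ((10, 8), [(1, 4, 1)]),
        ((9,), []),
    ])
    def test_examples(self, lengths, expected):
        exons, cursor = [], 0
        for i, ln in enumerate(lengths):
            exons.append(ExonInterval(start=cursor, end=cursor + ln, rank=i + 1))
            cursor += ln + 50
        model = GeneModel(gene_id="g", taxon="t", strand="+", genome_id="G",
                          exons=exons)
        got = [(p.intron_rank, p.codon_index, p.phase)
               for p in intron_positions(model)]
        assert got == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=40),
                    min_size=1, max_size=6).filter(lambda ls: sum(ls) % 3 == 0))
    def test_resegmentation_oracle(self, lengths):
        """Mapping every transcript nucleotide to its codon reproduces the
        (codon_index, phase) of each junction."""
        exons, cursor = [], 0
        for i, ln in enumerate(lengths):
            exons.append(ExonInterval(start=cursor, end=cursor + ln, rank=i + 1))
            cursor += ln + 10
        model = GeneModel(gene_id="g", taxon="t", strand="+", genome_id="G",
                          exons=exons)
        nt2codon = [(k // 3 + 1, k % 3) for k in range(sum(lengths))]
        expected, cum = [], 0
        for ln in lengths[:-1]:
            cum += ln
            expected.append(nt2codon[cum])  # codon hosting / following junction
        got = [(p.codon_index, p.phase) for p in intron_positions(model)]
        assert got == expected

    def test_protein_length_relation(self):
        """len(protein) == total exon length / 3 - 1 for stop-terminated CDS."""
        cds = "ATG" + "GCT" * 10 + "TAA"
        model, genome = build_gene(cds, [7, 20])
        assert len(spliced_protein(model, genome).residues) == \
            model.total_exon_length() // 3 - 1
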