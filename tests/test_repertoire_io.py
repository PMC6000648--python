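"""Annotation parsing and repertoire-matrix assembly."""

import pandas as pd
import pytest

from trnaevo.repertoire import (
    TRNAGene,
    absence_summary,
    build_repertoire_matrix,
    matrix_columns,
    parse_trna_annotations,
    read_matrix,
    write_matrix,
)
from trnaevo.decoding import core_repertoire, sense_anticodons


def make_gene(genome, anticodon, **kw):
    kw.setdefault("isotype", "")
    return TRNAGene(genome_id=genome, anticodon=anticodon, **kw)


class TestTrnascanParser:
    def test_three_line_fixture(self, trnascan_file):
        genes = parse_trna_annotations(trnascan_file, "trnascan_tabular")
        assert [g.anticodon for g in genes] == ["CAU", "GAG", "GAU"]
        assert genes[0].genome_id == "G900"

    def test_minus_strand_coordinates_normalized(self, trnascan_file):
        genes = parse_trna_annotations(trnascan_file, "trnascan_tabular")
        ile = genes[2]
        assert (ile.start, ile.end, ile.strand) == (529, 600, "-")

    def test_undetermined_anticodon_flagged_and_excluded(self, tmp_path):
        p = tmp_path / "G901.tsv"
        p.write_text("chr1\t1\t10\t80\tUndet\t???\t0\t0\t50.0\n")
        genes = parse_trna_annotations(p, "trnascan_tabular")
        assert genes[0].undetermined
        mat = build_repertoire_matrix(genes, ["G901"])
        assert mat.loc["G901"].sum() == 0

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chr1\t1\t10\n")
        with pytest.raises(ValueError, match="bad.tsv:1"):
            parse_trna_annotations(p, "trnascan_tabular")

    def test_intron_bounds_become_gene_relative(self, tmp_path):
        p = tmp_path / "G902.tsv"
        p.write_text("chr1\t1\t100\t190\tIle\tTAT\t137\t150\t60.0\n")
        (gene,) = parse_trna_annotations(p, "trnascan_tabular")
        assert gene.intron_intervals == [(38, 51)]


class TestGff3Parser:
    def test_minus_strand_anticodon_reported_as_annotated(self, tmp_path):
        p = tmp_path / "G903.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsim\ttRNA\t100\t171\t.\t-\t.\tID=t1;anticodon=GAG;isotype=Leu\n"
        )
        (gene,) = parse_trna_annotations(p, "gff3")
        assert gene.anticodon == "GAG" and gene.strand == "-"

    def test_intron_child_feature_attached(self, tmp_path):
        p = tmp_path / "G904.gff3"
        p.write_text(
            "chr1\tsim\ttRNA\t100\t190\t.\t+\t.\tID=t1;anticodon=UAU;isotype=Ile\n"
            "chr1\tsim\tintron\t137\t150\t.\t+\t.\tParent=t1\n"
        )
        (gene,) = parse_trna_annotations(p, "gff3")
        assert gene.intron_intervals == [(38, 51)]


class TestFastaParser:
    def test_header_and_sequence(self, tmp_path):
        p = tmp_path / "G905.fasta"
        p.write_text(">t1 Leu (GAG) 8 bp\nACGTACGT\n")
        (gene,) = parse_trna_annotations(p, "gtrnadb_fasta")
        assert gene.anticodon == "GAG"
        assert gene.sequence == "ACGUACGU"

    def test_imet_tag_recognized(self, tmp_path):
        p = tmp_path / "G906.fasta"
        p.write_text(">t1 iMet (CAT) 4 bp\nACGT\n>t2 eMet (CAT) 4 bp\nACGT\n")
        genes = parse_trna_annotations(p, "gtrnadb_fasta")
        assert [g.met_tag for g in genes] == ["iMet", "eMet"]


class TestMatrix:
    def test_one_gene_per_sense_anticodon_gives_row_of_ones(self, code):
        genes = [make_gene("g1", a) for a in sense_anticodons(code)]
        mat = build_repertoire_matrix(genes, ["g1"])
        assert mat.shape == (1, 61)
        assert (mat.loc["g1"] == 1).all()

    def test_core_repertoire_has_17_absent_types(self, code):
        genes = [make_gene("g1", a) for a in core_repertoire(code)]
        mat = build_repertoire_matrix(genes, ["g1"])
        per_genome, _ = absence_summary(mat)
        assert per_genome.loc["g1", "types_absent"] == 17
        assert per_genome.loc["g1", "types_present"] == 44

    def test_met_split_counts_tags(self):
        genes = [
            make_gene("g1", "CAU", met_tag="iMet"),
            make_gene("g1", "CAU", met_tag="eMet"),
            make_gene("g1", "CAU", met_tag="eMet"),
        ]
        mat = build_repertoire_matrix(genes, ["g1"], split_met=True)
        assert mat.loc["g1", "iMet-CAU"] == 1
        assert mat.loc["g1", "eMet-CAU"] == 2
        unsplit = build_repertoire_matrix(genes, ["g1"], split_met=False)
        assert unsplit.loc["g1", "Met-CAU"] == 3

    def test_split_columns_sum_to_unsplit_cau(self):
        assert len(matrix_columns(split_met=True)) == 62

    def test_pseudogene_excluded_by_default(self):
        genes = [make_gene("g1", "GAG", pseudo=True), make_gene("g1", "GAG")]
        assert build_repertoire_matrix(genes, ["g1"]).loc["g1", "Leu-GAG"] == 1
        assert build_repertoire_matrix(genes, ["g1"], include_pseudo=True).loc[
            "g1", "Leu-GAG"
        ] == 2

    def test_stop_decoding_anticodon_excluded_with_warning(self):
        genes = [make_gene("g1", "CUA"), make_gene("g1", "GAG")]
        with pytest.warns(UserWarning, match="stop"):
            mat = build_repertoire_matrix(genes, ["g1"])
        assert mat.loc["g1"].sum() == 1

    def test_empty_genome_warns_and_yields_zero_row(self):
        genes = [make_gene("g1", "GAG")]
        with pytest.warns(UserWarning, match="zero counted"):
            mat = build_repertoire_matrix(genes, ["g1", "g2"])
        assert mat.loc["g2"].sum() == 0

    def test_unknown_genome_rejected(self):
        with pytest.raises(ValueError, match="unknown genome"):
            build_repertoire_matrix([make_gene("gX", "GAG")], ["g1"])

    def test_row_sums_equal_accepted_gene_counts(self, rng, code):
        pool = sorted(sense_anticodons(code))
        genomes = [f"g{i}" for i in range(5)]
        genes = []
        accepted = {g: 0 for g in genomes}
        for g in genomes:
            for a in rng.choice(pool, size=rng.integers(5, 60)):
                pseudo = bool(rng.random() < 0.1)
                genes.append(make_gene(g, str(a), pseudo=pseudo))
                if not pseudo:
                    accepted[g] += 1
        mat = build_repertoire_matrix(genes, genomes)
        for g in genomes:
            assert mat.loc[g].sum() == accepted[g]


class TestAbsenceSummary:
    def test_all_ones_matrix_has_no_absences(self):
        mat = pd.DataFrame(1, index=["a", "b"], columns=matrix_columns())
        per_genome, per_type = absence_summary(mat)
        assert (per_genome["types_absent"] == 0).all()
        assert (per_type == 0).all()

    def test_all_zero_type_lacking_in_every_genome(self):
        mat = pd.DataFrame(1, index=["a", "b", "c"], columns=matrix_columns())
        mat["Leu-GAG"] = 0
        _, per_type = absence_summary(mat)
        assert per_type["Leu-GAG"] == 3

    def test_matches_naive_per_cell_recount(self, rng):
        cols = matrix_columns()
        mat = pd.DataFrame(
            rng.integers(0, 3, size=(6, len(cols))), index=[f"g{i}" for i in range(6)],
            columns=cols,
        )
        per_genome, per_type = absence_summary(mat)
        for g in mat.index:
            present = sum(1 for c in cols if mat.loc[g, c] > 0)
            assert per_genome.loc[g, "types_present"] == present
            assert per_genome.loc[g, "types_absent"] == len(cols) - present
            assert per_genome.loc[g, "total_copies"] == mat.loc[g].sum()
        for c in cols:
            assert per_type[c] == sum(1 for g in mat.index if mat.loc[g, c] == 0)


def test_matrix_tsv_round_trip_is_bit_exact(tmp_path, rng):
    cols = matrix_columns()
    mat = pd.DataFrame(
        rng.integers(0, 5, size=(4, len(cols))), index=[f"g{i}" for i in range(4)],
        columns=cols,
    ).rename_axis("genome_id")
    p1, p2 = tmp_path / "m1.tsv", tmp_path / "m2.tsv"
    write_matrix(mat, p1)
    back = read_matrix(p1)
    pd.testing.assert_frame_equal(mat, back)
    write_matrix(back, p2)
    assert p1.read_bytes() == p2.read_bytes()
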