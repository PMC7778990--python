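import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tboxkit.errors import ParseError, StructureFormatError
from tboxkit.genetics import normalize_rna
from tboxkit.seqio import (
    TBDB_COLUMNS,
    StructureSearchHit,
    TrnaRecord,
    discriminator_of,
    format_interval,
    from_source_coords,
    parse_interval,
    read_fasta,
    read_structure_hits,
    read_tbdb_csv,
    read_trnas,
    to_source_coords,
    write_aligned_hits,
    write_fasta,
    write_tbdb_csv,
)


class TestReadFasta:
    def test_t_is_normalized_to_u(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nACGT\n")
        (rec,) = read_fasta(p)
        assert rec.sequence == "ACGU"
        assert rec.record_id == "x"

    def test_multiple_records_keep_header_order(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACGU\n>b\nGGGG\n")
        recs = read_fasta(p)
        assert [r.record_id for r in recs] == ["a", "b"]

    def test_gap_character_raises_parse_error(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nAC-GU\n")
        with pytest.raises(ParseError, match="x"):
            read_fasta(p)

    def test_empty_file_yields_empty_list(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        assert read_fasta(p) == []

    def test_host_and_annotation_round_trip(self, tmp_path, corpus20):
        p = tmp_path / "out.fasta"
        write_fasta(corpus20.records, p)
        back = read_fasta(p)
        assert [(r.record_id, r.host_name, r.sequence, r.downstream_annotation)
                for r in back] == [
            (r.record_id, r.host_name, r.sequence, r.downstream_annotation)
            for r in corpus20.records
        ]


class TestStructureHits:
    def test_tabular_minus_strand_flips_coordinates(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("# comment line\nrec1 modelA 90 31 - 55.2\n")
        (hit,) = read_structure_hits(p, dialect="tabular")
        assert (hit.target_start, hit.target_end, hit.strand) == (30, 90, "-")
        assert hit.target_start < hit.target_end

    def test_tabular_zero_hits(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("# only comments\n\n")
        assert read_structure_hits(p, dialect="tabular") == []

    def test_unknown_dialect_is_a_usage_error(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("")
        with pytest.raises(ValueError, match="dialect"):
            read_structure_hits(p, dialect="bogus")

    def test_aligned_round_trip_preserves_consensus(self, tmp_path, corpus20):
        p = tmp_path / "hits.sto"
        write_aligned_hits(corpus20.hits, p)
        back = read_structure_hits(p, dialect="aligned")
        assert len(back) == len(corpus20.hits)
        for a, b in zip(corpus20.hits, back):
            assert a.consensus_structure == b.consensus_structure
            assert a.aligned_sequence == b.aligned_sequence
            assert (a.target_id, a.target_start, a.target_end) == (
                b.target_id, b.target_start, b.target_end)

    def test_unbalanced_consensus_rejected(self):
        with pytest.raises(StructureFormatError, match="unclosed"):
            StructureSearchHit(
                query_model="m", target_id="t", target_start=0, target_end=4,
                consensus_structure="((..", aligned_sequence="ACGU",
            )


class TestTrnas:
    def _scanner_file(self, tmp_path, rows):
        header = ("Sequence\t\t\ttRNA\tBounds\nName\ttRNA #\tBegin\tEnd\tType\t"
                  "Codon\tBegin\tEnd\tScore\n--------\t------\t----\t---\t----\t"
                  "-----\t-----\t----\t-----\n")
        p = tmp_path / "trnas.txt"
        p.write_text(header + "".join(rows))
        return p

    def test_family_filled_from_anticodon(self, tmp_path):
        p = self._scanner_file(
            tmp_path,
            ["host1\t1\t10\t82\tUndet\tCCA\t0\t0\t80.1\n",
             "host1\t2\t100\t172\tUndet\tGAU\t0\t0\t70.0\n"],
        )
        recs = read_trnas(p, dialect="scanner_tabular")
        assert [r.family for r in recs] == ["W", "I"]

    def test_bad_anticodon_skipped_with_warning(self, tmp_path, caplog):
        p = self._scanner_file(
            tmp_path,
            ["host1\t1\t10\t82\tTrp\tCCA\t0\t0\t80.1\n",
             "host1\t2\t100\t172\tUndet\tNNN\t0\t0\t70.0\n"],
        )
        with caplog.at_level(logging.WARNING):
            recs = read_trnas(p, dialect="scanner_tabular")
        assert len(recs) == 1 and recs[0].anticodon == "CCA"
        assert any("skip" in m.lower() for m in caplog.messages)

    @pytest.mark.parametrize(
        "sequence, expected",
        [("GGGAUCGAUCGUCCA", "U"),   # base 5' of the 3'-terminal CCA
         ("GGGAUCGAUCG", "G"),       # no CCA: 3'-terminal base
         ("", None)],
    )
    def test_discriminator_rule(self, sequence, expected):
        assert discriminator_of(sequence) == expected

    def test_fasta_meta_round_trip(self, tmp_path, corpus20):
        from tboxkit.seqio import write_trna_fasta
        p = tmp_path / "trnas.fasta"
        write_trna_fasta(corpus20.trnas, p)
        back = read_trnas(p, dialect="fasta_meta")
        assert [(t.host_name, t.anticodon, t.family, t.discriminator)
                for t in back] == [
            (t.host_name, t.anticodon, t.family, t.discriminator)
            for t in corpus20.trnas
        ]


class TestTbdbCsv:
    def test_round_trip_is_identity(self, tmp_path, report20):
        rows = [r.to_row() for r in report20.results]
        p = tmp_path / "tbdb.csv"
        assert write_tbdb_csv(rows, p, header_comments=["k = v"]) == len(rows)
        assert read_tbdb_csv(p) == rows

    def test_missing_prediction_fields_become_empty(self, tmp_path):
        p = tmp_path / "tbdb.csv"
        write_tbdb_csv([{"id": "x", "sequence": "ACGU"}], p)
        (row,) = read_tbdb_csv(p)
        assert row["id"] == "x"
        assert row["terminator_interval"] == ""
        assert set(row) == set(TBDB_COLUMNS)

    def test_empty_input_writes_header_only(self, tmp_path):
        p = tmp_path / "tbdb.csv"
        assert write_tbdb_csv([], p) == 0
        assert read_tbdb_csv(p) == []
        assert p.read_text().strip() == ",".join(TBDB_COLUMNS)


@given(start=st.integers(1, 10_000), length=st.integers(1, 500),
       strand=st.sampled_from("+-"))
@settings(max_examples=100, derandomize=True)
def test_source_coordinate_conversion_round_trips(start, length, strand):
    end = start + length - 1
    s1, e1 = (start, end) if strand == "+" else (end, start)
    s0, e0, derived = from_source_coords(s1, e1)
    assert s0 < e0 and e0 - s0 == length
    assert to_source_coords(s0, e0, derived) == (s1, e1)


@given(st.text(alphabet="ACGTUacgtu", max_size=50))
@settings(max_examples=100, derandomize=True)
def test_t_u_normalization_is_idempotent(s):
    once = normalize_rna(s)
    assert normalize_rna(once) == once
    assert "T" not in once


@given(st.integers(0, 1000), st.integers(1, 500))
@settings(max_examples=50, derandomize=True)
def test_interval_formatting_round_trips(start, length):
    assert parse_interval(format_interval((start, start + length))) == (
        start, start + length)
    assert parse_interval(format_interval(None)) is None
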