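"""Sequence families, helix windows, FASTA and config I/O."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helixvote import (
    ConfigurationError,
    FastaParseError,
    HelixWindow,
    OUT_OF_RANGE,
    ProfileFamily,
    SequenceRecord,
    ValidationError,
    extract_window,
    load_helix_config,
    read_fasta,
    write_fasta,
)


class TestSequenceRecord:
    def test_rejects_whitespace_id(self):
        with pytest.raises(ValidationError):
            SequenceRecord("bad id", "MVLS")

    def test_rejects_empty_sequence(self):
        with pytest.raises(ValidationError):
            SequenceRecord("ok", "")


class TestHelixWindow:
    def test_adgb_helix_a_span_has_length_13(self):
        # helix A of the androglobin globin domain runs Val939-Glu951
        w = HelixWindow("A", "Adgb", 939, 951)
        assert len(w) == 13

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(helix_id="Z", family_id="f", start=1, end=10),
            dict(helix_id="A", family_id="f", start=10, end=9),
            dict(helix_id="A", family_id="f", start=10, end=10),  # length 1 < 4
            dict(helix_id="A", family_id="f", start=0, end=10),
        ],
    )
    def test_invalid_windows_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            HelixWindow(**kwargs)


class TestProfileFamily:
    def test_duplicate_ids_rejected(self):
        recs = [SequenceRecord("a", "MVLS"), SequenceRecord("a", "MVHL")]
        with pytest.raises(ValidationError, match="duplicate"):
            ProfileFamily("f", recs)

    def test_aligned_flag_requires_equal_lengths(self):
        recs = [SequenceRecord("a", "MVLS"), SequenceRecord("b", "MV")]
        with pytest.raises(ValidationError, match="aligned"):
            ProfileFamily("f", recs, is_aligned=True)

    def test_alignment_column_window_requires_alignment(self):
        recs = [SequenceRecord("a", "MVLSPADK")]
        w = HelixWindow("A", "f", 1, 4, coordinate_space="alignment-column")
        with pytest.raises(ConfigurationError):
            ProfileFamily("f", recs, windows={"A": w}, is_aligned=False)

    def test_window_beyond_alignment_width_rejected(self):
        recs = [SequenceRecord("a", "MVLS")]
        w = HelixWindow("A", "f", 1, 6)
        with pytest.raises(ValidationError, match="width"):
            ProfileFamily("f", recs, windows={"A": w}, is_aligned=True)


class TestFasta:
    def test_reads_records_in_order(self, tmp_path):
        p = tmp_path / "fam.fasta"
        p.write_text(">s1\nMVLS\n>s2\nMVHL\n")
        fam = read_fasta(p)
        assert [r.residues for r in fam.records] == ["MVLS", "MVHL"]
        assert fam.family_id == "fam"

    def test_illegal_character_names_record_and_position(self, tmp_path):
        p = tmp_path / "f.fasta"
        p.write_text(">s1\nMV7S\n")
        with pytest.raises(ValidationError, match=r"s1.*'7'.*position 3"):
            read_fasta(p)

    def test_gap_rejected_unless_allowed(self, tmp_path):
        p = tmp_path / "f.fasta"
        p.write_text(">s1\nMV-S\n>s2\nMVLS\n")
        with pytest.raises(ValidationError):
            read_fasta(p)
        fam = read_fasta(p, allow_gaps=True)
        assert fam.is_aligned and fam.records[0].residues == "MV-S"

    def test_malformed_header_names_line(self, tmp_path):
        p = tmp_path / "f.fasta"
        p.write_text("MVLS\n>s1\nMVHL\n")
        with pytest.raises(FastaParseError, match="line 1"):
            read_fasta(p)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "f.fasta"
        p.write_text(">s1\nMVLS\n>s1\nMVHL\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_fasta(p)

    def test_many_entry_family_size(self, tmp_path):
        p = tmp_path / "big.fasta"
        p.write_text("".join(f">s{i}\nMVLSPADKTNVKAAW\n" for i in range(235)))
        assert len(read_fasta(p)) == 235

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seqs=st.lists(
            st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40),
            min_size=1,
            max_size=8,
        )
    )
    def test_write_then_read_round_trips(self, tmp_path_factory, seqs):
        fam = ProfileFamily(
            "rt", [SequenceRecord(f"r{i}", s) for i, s in enumerate(seqs)]
        )
        path = tmp_path_factory.mktemp("fasta") / "rt.fasta"
        write_fasta(fam, path)
        back = read_fasta(path, family_id="rt")
        assert [(r.id, r.residues) for r in back.records] == [
            (r.id, r.residues) for r in fam.records
        ]


class TestHelixConfig:
    def test_tsv_round_trip(self, tmp_path):
        p = tmp_path / "helices.tsv"
        p.write_text(
            "family_id\thelix_id\tstart\tend\tcoordinate_space\n"
            "Adgb\tA\t939\t951\tsequence\n"
            "Adgb\tH\t866\t877\tsequence\n"
            "Adgb\tIQ\t891\t933\tsequence\n"
        )
        cfg = load_helix_config(p)
        assert len(cfg["Adgb"]["A"]) == 13
        assert len(cfg["Adgb"]["H"]) == 12
        assert len(cfg["Adgb"]["IQ"]) == 43

    def test_yaml_with_partial_helices_accepted(self, tmp_path):
        # C and D are not voted on; families may omit them
        p = tmp_path / "helices.yaml"
        p.write_text(
            "alphaHb:\n"
            "  A: {start: 4, end: 18, coordinate_space: sequence}\n"
            "  B: [21, 35]\n"
        )
        cfg = load_helix_config(p)
        assert set(cfg["alphaHb"]) == {"A", "B"}
        assert cfg["alphaHb"]["B"].coordinate_space == "alignment-column"

    def test_invalid_spans_rejected(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("family_id\thelix_id\tstart\tend\nf\tA\t10\t9\n")
        with pytest.raises(ValidationError):
            load_helix_config(p)
        p.write_text("family_id\thelix_id\tstart\tend\nf\tQ\t1\t10\n")
        with pytest.raises(ValidationError, match="helix"):
            load_helix_config(p)


class TestExtractWindow:
    REC = SequenceRecord("r", "MVLSPADK")
    W = HelixWindow("A", "f", 2, 5, coordinate_space="sequence")

    def test_zero_shift_is_plain_substring(self):
        assert extract_window(self.REC, self.W, 0) == "VLSP"

    def test_left_edge_truncation_marks_out_of_range(self):
        w = HelixWindow("A", "f", 2, 5, coordinate_space="sequence")
        assert extract_window(self.REC, w, -2) == OUT_OF_RANGE + "MVL"

    def test_right_edge_fully_out_of_range(self):
        w = HelixWindow("A", "f", 5, 8, coordinate_space="sequence")
        assert extract_window(self.REC, w, 4) == OUT_OF_RANGE * 4

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=12, max_size=60),
        start=st.integers(1, 6),
        length=st.integers(4, 6),
        s1=st.integers(-10, 10),
        s2=st.integers(-10, 10),
    )
    def test_shifts_differ_by_a_pure_slide(self, seq, start, length, s1, s2):
        """In-range positions shared by two shifts carry identical residues."""
        rec = SequenceRecord("r", seq)
        w = HelixWindow("A", "f", start, start + length - 1, coordinate_space="sequence")
        w1, w2 = extract_window(rec, w, s1), extract_window(rec, w, s2)
        for i, ch in enumerate(w1):
            j = i + s1 - s2  # same absolute position in the other extraction
            if 0 <= j < len(w2) and ch != OUT_OF_RANGE and w2[j] != OUT_OF_RANGE:
                assert ch == w2[j]
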