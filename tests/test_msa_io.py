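"""MSA reading, filtering, weighting and PSSM parsing."""

import numpy as np
import pytest

from rescue import (
    Alignment,
    FormatError,
    ParameterError,
    compute_weights,
    dedupe_by_query_identity,
    filter_coverage,
    filter_gap_columns,
    profile_from_alignment,
    read_msa,
    read_pssm,
    write_msa,
)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadMSA:
    def test_fasta_identity_parse(self, tmp_path):
        p = write(tmp_path, "a.fasta",
                  ">q\nACDEFGHI\n>s1\nACDEFGH-\n>s2\nAC-EFGHI\n")
        aln = read_msa(p, format="fasta")
        assert (aln.M, aln.L) == (3, 8)
        assert aln.query == "ACDEFGHI"
        assert aln.column_map == list(range(8))

    def test_a3m_inserts_dropped(self, tmp_path):
        # record 2 carries lowercase insert states; after normalization all
        # records have the query's 6 columns
        p = write(tmp_path, "a.a3m",
                  ">q\nACDEFG\n>s1\nACDEFG\n>s2\nACdefDEFG\n")
        aln = read_msa(p, format="a3m")
        assert (aln.M, aln.L) == (3, 6)
        assert aln.records[2][1] == "ACDEFG"

    def test_empty_file_is_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            read_msa(write(tmp_path, "e.fasta", ""), format="fasta")

    def test_ragged_a3m_is_format_error(self, tmp_path):
        p = write(tmp_path, "r.a3m", ">q\nACDEFG\n>s1\nACDE\n")
        with pytest.raises(FormatError):
            read_msa(p, format="a3m")

    def test_stockholm(self, tmp_path):
        p = write(tmp_path, "a.sto",
                  "# STOCKHOLM 1.0\nq ACDEF\ns1 ACDE-\n//\n")
        aln = read_msa(p, format="stockholm")
        assert (aln.M, aln.L) == (2, 5)

    def test_query_gap_columns_dropped_and_mapped(self, tmp_path):
        p = write(tmp_path, "g.fasta", ">q\nAC-EF\n>s1\nACDEF\n")
        aln = read_msa(p)
        assert aln.L == 4
        assert aln.records[1][1] == "ACEF"

    def test_nonstandard_letters_become_x(self, tmp_path):
        p = write(tmp_path, "x.fasta", ">q\nACDEF\n>s1\nABZEF\n")
        aln = read_msa(p)
        assert aln.records[1][1] == "AXXEF"

    def test_roundtrip_write(self, tmp_path):
        p = write(tmp_path, "a.fasta", ">q\nACDEF\n>s1\nAC-EF\n")
        aln = read_msa(p)
        out = tmp_path / "out.fasta"
        write_msa(aln, out)
        assert read_msa(out).records == aln.records


class TestFilters:
    def test_coverage_boundary_inclusive(self):
        # 6 of 8 non-gap = exactly 75%: retained ("at least 75%")
        aln = Alignment(records=[("q", "ACDEFGHI"), ("s", "ACDEFG--")])
        assert filter_coverage(aln, 0.75).M == 2

    def test_coverage_below_threshold_dropped(self):
        aln = Alignment(records=[("q", "ACDEFGHI"), ("s", "ACDEF---")])
        out = filter_coverage(aln, 0.75)
        assert out.M == 1 and out.query == "ACDEFGHI"

    def test_coverage_full_length_identity(self):
        aln = Alignment(records=[("q", "ACDE"), ("s", "MKVS")])
        assert filter_coverage(aln).records == aln.records

    def test_coverage_never_drops_query(self):
        aln = Alignment(records=[("s", "ACDEFGHI"), ("q", "A-------")],
                        query_index=1)
        out = filter_coverage(aln, 0.75)
        assert out.records[out.query_index][0] == "q"

    def test_coverage_bad_parameter(self):
        aln = Alignment(records=[("q", "ACDE")])
        with pytest.raises(ParameterError):
            filter_coverage(aln, 0.0)

    def test_gap_column_boundary_strict(self):
        # column 2: 3/4 gaps = 75% exactly -> retained ("more than 75%")
        aln = Alignment(records=[("q", "ACD"), ("a", "AC-"),
                                 ("b", "AC-"), ("c", "AC-")])
        assert filter_gap_columns(aln, 0.75).L == 3

    def test_gap_column_removed_and_mapped(self):
        # column 1: 4/5 gaps = 80% -> removed; column_map skips it
        aln = Alignment(records=[("q", "ACD"), ("a", "A-D"), ("b", "A-D"),
                                 ("c", "A-D"), ("d", "A-D")])
        out = filter_gap_columns(aln, 0.75)
        assert out.L == 2
        assert out.column_map == [0, 2]
        assert out.query_length == 3

    def test_gap_free_identity_column_map(self):
        aln = Alignment(records=[("q", "ACD"), ("a", "ACD")])
        assert filter_gap_columns(aln).column_map == [0, 1, 2]

    @pytest.mark.parametrize("filt,kwargs", [
        (filter_coverage, {"min_coverage": 0.75}),
        (filter_gap_columns, {"max_gap_fraction": 0.75}),
    ])
    def test_filters_idempotent(self, filt, kwargs):
        aln = Alignment(records=[
            ("q", "ACDEFGHI"), ("a", "ACDEFG--"), ("b", "A----GHI"),
            ("c", "-C-E-G-I"), ("d", "ACDEFGH-")])
        once = filt(aln, **kwargs)
        twice = filt(once, **kwargs)
        assert twice.records == once.records
        assert twice.column_map == once.column_map

    def test_both_filters_identity_on_gap_free(self):
        aln = Alignment(records=[("q", "ACDE"), ("a", "MKVS"), ("b", "WYHT")])
        out = filter_coverage(filter_gap_columns(aln))
        assert out.records == aln.records and out.column_map == aln.column_map


class TestWeights:
    def test_all_identical(self):
        aln = Alignment(records=[(f"s{k}", "ACDE") for k in range(4)])
        out = compute_weights(aln)
        assert np.allclose(out.weights, 0.25)
        assert out.meff == pytest.approx(1.0)

    def test_all_distinct(self):
        aln = Alignment(records=[("a", "AAAAA"), ("b", "CCCCC"),
                                 ("c", "DDDDD")])
        out = compute_weights(aln)
        assert np.allclose(out.weights, 1.0)
        assert out.meff == pytest.approx(3.0)

    def test_two_identical_two_unique(self):
        aln = Alignment(records=[("a", "AAAAA"), ("b", "AAAAA"),
                                 ("c", "CCCCC"), ("d", "DDDDD")])
        out = compute_weights(aln)
        assert np.allclose(out.weights, [0.5, 0.5, 1.0, 1.0])
        assert out.meff == pytest.approx(3.0)

    def test_meff_bounds(self):
        rng = np.random.default_rng(0)
        letters = np.array(list("ACDE"))
        recs = [("q", "AAAAAAAA")] + [
            (f"s{k}", "".join(rng.choice(letters, 8))) for k in range(9)]
        out = compute_weights(Alignment(records=recs))
        assert 1.0 < out.meff <= out.M

    def test_dedupe_by_query_identity(self):
        aln = Alignment(records=[("q", "AAAAA"), ("near", "AAAAC"),
                                 ("far", "CCCCC")])
        out = dedupe_by_query_identity(aln, 0.75)
        assert [n for n, _ in out.records] == ["q", "far"]


class TestPSSM:
    def test_read_hand_fixture(self, pssm_file):
        prof = read_pssm(pssm_file)
        assert prof.scores.shape == (5, 20)
        # position 1 is M: +8 on M, -1 on A (canonical column order)
        assert prof.score(0, "M") == 8
        assert prof.score(0, "A") == -1
        assert prof.score(4, "W") == 11

    def test_header_only_is_format_error(self, tmp_path):
        p = tmp_path / "h.pssm"
        p.write_text("   A R N D C Q E G H I L K M F P S T W Y V\n")
        with pytest.raises(FormatError):
            read_pssm(p)

    def test_bad_numbering_is_format_error(self, tmp_path, pssm_file):
        text = pssm_file.read_text().replace("    2 K", "    7 K")
        p = tmp_path / "bad.pssm"
        p.write_text(text)
        with pytest.raises(FormatError):
            read_pssm(p)

    def test_non_numeric_cell_is_format_error(self, tmp_path, pssm_file):
        text = pssm_file.read_text().replace(" 11   2", " xx   2")
        p = tmp_path / "bad2.pssm"
        p.write_text(text)
        with pytest.raises(FormatError):
            read_pssm(p)


def test_profile_from_alignment_prefers_consensus():
    aln = Alignment(records=[("a", "AC"), ("b", "AC"), ("c", "AD")])
    prof = profile_from_alignment(aln)
    assert prof.score(0, "A") > prof.score(0, "C")
    assert prof.score(1, "C") > prof.score(1, "D")
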