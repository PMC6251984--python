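"""CIGAR algebra: parsing, MSA round trips, column classes, statistics."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from famviz.cigar_core import (
    AlignmentCigar,
    ColumnClass,
    cigars_from_msa,
    classify_columns,
    default_scoring_matrix,
    pairwise_stats,
    parse_cigar,
    rebuild_row,
)
from famviz.errors import CigarError, ModelError

from _oracles import classify_brute, random_cigar_pair, stats_brute


class TestParseCigar:
    @pytest.mark.parametrize(
        "text,runs,length",
        [
            ("4M2D3M", ((4, "M"), (2, "D"), (3, "M")), 9),
            ("MDM", ((1, "M"), (1, "D"), (1, "M")), 3),
            ("7M", ((7, "M"),), 7),
            ("2M2M", ((4, "M"),), 4),  # normalization merges adjacent runs
        ],
    )
    def test_runs_and_length(self, text, runs, length):
        cig = parse_cigar(text)
        assert cig.runs == runs
        assert cig.alignment_length == length

    def test_unsupported_op_named(self):
        with pytest.raises(CigarError, match="X"):
            parse_cigar("5X")

    @pytest.mark.parametrize("bad", ["", "   ", "3", "M3"])
    def test_malformed(self, bad):
        with pytest.raises(CigarError):
            parse_cigar(bad)

    def test_str_roundtrip(self):
        for text in ("4M2D3M", "MDM", "7M"):
            cig = parse_cigar(text)
            assert parse_cigar(str(cig)).runs == cig.runs


class TestMsaConversion:
    def test_simple_row(self):
        cigars, seqs = cigars_from_msa({"x": "MK--VL"})
        assert str(cigars["x"]) == "2M2D2M"
        assert seqs["x"] == "MKVL"

    def test_gapless_row(self):
        cigars, _ = cigars_from_msa({"x": "MKVLQTW"})
        assert str(cigars["x"]) == "7M"

    def test_ragged_msa_rejected(self):
        with pytest.raises(CigarError, match="ragged"):
            cigars_from_msa({"x": "MKV", "y": "MK"})

    def test_all_gap_row_named(self):
        with pytest.raises(CigarError, match="y"):
            cigars_from_msa({"x": "MKV", "y": "---"})

    def test_rebuild_reproduces_rows(self):
        """Round trip on 50 random MSAs (direct string reconstruction)."""
        rng = random.Random(42)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(50):
            width = rng.randint(3, 60)
            rows = {}
            for m in range(rng.randint(2, 6)):
                row = "".join(
                    rng.choice(aas) if rng.random() > 0.3 else "-"
                    for _ in range(width)
                )
                if set(row) == {"-"}:
                    row = rng.choice(aas) + row[1:]
                rows[f"m{m}"] = row
            cigars, seqs = cigars_from_msa(rows)
            for m, row in rows.items():
                assert rebuild_row(cigars[m], seqs[m]) == row


class TestClassifyColumns:
    def test_insertion_between_matches(self):
        got = classify_columns(parse_cigar("2M2D2M"), parse_cigar("6M"))
        assert got.runs == (
            (2, ColumnClass.BOTH), (2, ColumnClass.INSERTION), (2, ColumnClass.BOTH),
        )

    def test_identity(self):
        got = classify_columns(parse_cigar("5M"), parse_cigar("5M"))
        assert got.runs == ((5, ColumnClass.BOTH),)

    def test_pure_deletion(self):
        got = classify_columns(parse_cigar("3M"), parse_cigar("3D"))
        assert got.runs == ((3, ColumnClass.DELETION),)

    def test_length_mismatch_reports_both(self):
        with pytest.raises(ModelError, match="4.*7|7.*4"):
            classify_columns(parse_cigar("4M"), parse_cigar("7M"))

    def test_matches_brute_force(self):
        rng = random.Random(7)
        for _ in range(300):
            a, b = random_cigar_pair(rng)
            assert classify_columns(a, b).expand() == classify_brute(a, b)

    def test_swap_exchanges_indel_roles(self):
        rng = random.Random(8)
        swap = {
            ColumnClass.INSERTION: ColumnClass.DELETION,
            ColumnClass.DELETION: ColumnClass.INSERTION,
            ColumnClass.BOTH: ColumnClass.BOTH,
            ColumnClass.NEITHER: ColumnClass.NEITHER,
        }
        for _ in range(200):
            a, b = random_cigar_pair(rng)
            fwd = classify_columns(a, b).expand()
            rev = classify_columns(b, a).expand()
            assert [swap[c] for c in fwd] == rev


def _random_aligned_pair(rng):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    n = rng.randint(2, 50)
    rows = {}
    for name in ("a", "b"):
        row = "".join(
            rng.choice(aas) if rng.random() > 0.35 else "-" for _ in range(n)
        )
        if set(row) == {"-"}:
            row = rng.choice(aas) + row[1:]
        rows[name] = row
    return cigars_from_msa(rows)


class TestPairwiseStats:
    def test_identical_members(self):
        cigars, seqs = cigars_from_msa({"a": "MKV", "b": "MKV"})
        s = pairwise_stats(cigars["a"], seqs["a"], cigars["b"], seqs["b"])
        assert (
            s.perc_id_a == s.perc_id_b == s.perc_pos_a == s.perc_pos_b
            == s.perc_cov_a == s.perc_cov_b == 100.0
        )

    def test_asymmetric_lengths(self):
        cigars, seqs = cigars_from_msa({"a": "MKV-", "b": "MKVL"})
        s = pairwise_stats(cigars["a"], seqs["a"], cigars["b"], seqs["b"])
        assert s.perc_cov_a == 100.0 and s.perc_cov_b == 75.0
        assert s.perc_id_a == 100.0 and s.perc_id_b == 75.0

    def test_positive_but_not_identical(self):
        # BLOSUM62(M, L) = 2 > 0: positive, not identical
        cigars, seqs = cigars_from_msa({"a": "M", "b": "L"})
        s = pairwise_stats(cigars["a"], seqs["a"], cigars["b"], seqs["b"])
        assert s.perc_id_a == s.perc_id_b == 0.0
        assert s.perc_pos_a == s.perc_pos_b == 100.0

    def test_unknown_residue_named(self):
        cigars, _ = cigars_from_msa({"a": "J", "b": "M"})
        with pytest.raises(ModelError, match="J"):
            pairwise_stats(cigars["a"], "J", cigars["b"], "M")

    def test_matches_brute_force_and_ordering(self):
        rng = random.Random(13)
        matrix = default_scoring_matrix()
        for _ in range(120):
            cigars, seqs = _random_aligned_pair(rng)
            s = pairwise_stats(cigars["a"], seqs["a"], cigars["b"], seqs["b"])
            want = stats_brute(cigars["a"], seqs["a"], cigars["b"], seqs["b"], matrix)
            for key, val in want.items():
                assert getattr(s, key) == pytest.approx(val, abs=1e-9)
            for side in ("a", "b"):
                pid = getattr(s, f"perc_id_{side}")
                ppos = getattr(s, f"perc_pos_{side}")
                pcov = getattr(s, f"perc_cov_{side}")
                assert 0.0 <= pid <= ppos <= pcov <= 100.0

    def test_member_swap_symmetry(self):
        rng = random.Random(14)
        for _ in range(40):
            cigars, seqs = _random_aligned_pair(rng)
            fwd = pairwise_stats(cigars["a"], seqs["a"], cigars["b"], seqs["b"])
            rev = pairwise_stats(cigars["b"], seqs["b"], cigars["a"], seqs["a"])
            assert fwd.swapped() == rev


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(1, 9), st.sampled_from("MD")), min_size=1, max_size=12))
def test_cigar_normalization_invariants(runs):
    """Any run list normalizes: no adjacent equal ops, counts preserved."""
    cig = AlignmentCigar(member_id="h", runs=tuple(runs))
    for (c1, o1), (c2, o2) in zip(cig.runs, cig.runs[1:]):
        assert o1 != o2
    assert cig.alignment_length == sum(c for c, _ in runs)
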