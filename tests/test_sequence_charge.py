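"""Sequence-mode charge profiling: closed-form values and invariants."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from phdelta import (
    DEFAULT_PKA_TABLE, PkaTable, SequenceError, UnknownResidueError,
    overall_charge_score, ph_scan_rank, residue_partial_charge,
    sequence_charge_profile,
)

TABLE = DEFAULT_PKA_TABLE


def hh_charge(polarity: str, pka: float, ph: float) -> float:
    """Independent closed-form evaluation of the titration curve."""
    if polarity == "acidic":
        return -1.0 / (1.0 + 10.0 ** (pka - ph))
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


class TestResiduePartialCharge:
    @pytest.mark.parametrize("aa,polarity", [
        ("D", "acidic"), ("E", "acidic"), ("C", "acidic"), ("Y", "acidic"),
        ("H", "basic"), ("K", "basic"), ("R", "basic"),
    ])
    def test_midpoint_and_offsets_match_closed_form(self, aa, polarity):
        pka = TABLE.pka_of(aa)
        sign = -1.0 if polarity == "acidic" else 1.0
        assert residue_partial_charge(aa, pka, TABLE) == pytest.approx(
            sign * 0.5, abs=1e-12)
        for offset in (-2.0, 2.0):
            ph = pka + offset
            if not (0 < ph < 14):
                continue
            assert residue_partial_charge(aa, ph, TABLE) == pytest.approx(
                hh_charge(polarity, pka, ph), abs=1e-12)

    def test_lysine_two_units_below_pka(self):
        # 1 / (1 + 10^-2) evaluated directly
        assert residue_partial_charge("K", TABLE.pka_of("K") - 2.0, TABLE) == \
            pytest.approx(1.0 / (1.0 + 10.0 ** (-2.0)), abs=1e-12)

    @pytest.mark.parametrize("aa", list("GAVLIPFMWSTNQ"))
    def test_non_ionizable_residues_are_exactly_zero(self, aa):
        assert residue_partial_charge(aa, 7.0, TABLE) == 0.0

    def test_ambiguity_codes_lenient_vs_strict(self):
        assert residue_partial_charge("X", 7.0, TABLE) == 0.0
        with pytest.raises(UnknownResidueError):
            residue_partial_charge("X", 7.0, TABLE, strict=True)
        with pytest.raises(UnknownResidueError):
            residue_partial_charge("J", 7.0, TABLE)

    @pytest.mark.parametrize("ph", [0.0, 14.5, -1.0])
    def test_ph_outside_open_interval_rejected(self, ph):
        with pytest.raises(ValueError):
            residue_partial_charge("D", ph, TABLE)

    @given(aa=st.sampled_from("DECYHKR"),
           ph=st.floats(min_value=0.01, max_value=13.99))
    @settings(max_examples=200, deadline=None)
    def test_charge_bounds_follow_polarity(self, aa, ph):
        charge = residue_partial_charge(aa, ph, TABLE)
        if TABLE.polarity[aa] == "acidic":
            assert -1.0 <= charge <= 0.0
        else:
            assert 0.0 <= charge <= 1.0


class TestSequenceChargeProfile:
    def test_identical_ph_values_give_zero_deltas_and_score(self):
        p = sequence_charge_profile("G", 7.0, 7.0, TABLE, include_termini=False)
        assert all(r.charge_ref == r.charge_int == 0.0 for r in p.residues)
        assert p.overall_charge_score == 0.0

    def test_two_residue_profile_matches_sum_of_closed_forms(self):
        p = sequence_charge_profile("DK", 7.0, 1.0, TABLE, include_termini=False)
        d_ref = hh_charge("acidic", 3.80, 7.0)
        d_int = hh_charge("acidic", 3.80, 1.0)
        k_ref = hh_charge("basic", 10.50, 7.0)
        k_int = hh_charge("basic", 10.50, 1.0)
        assert p.residues[0].charge_ref == pytest.approx(d_ref, abs=1e-12)
        assert p.residues[0].charge_int == pytest.approx(d_int, abs=1e-12)
        assert p.residues[1].charge_ref == pytest.approx(k_ref, abs=1e-12)
        expected = ((d_int + k_int) - (d_ref + k_ref)) / 2.0
        assert p.overall_charge_score == pytest.approx(expected, abs=1e-12)

    def test_non_ionizable_sequence_scores_zero_without_termini(self):
        p = sequence_charge_profile("GGG", 2.0, 12.0, TABLE, include_termini=False)
        assert p.overall_charge_score == 0.0

    def test_termini_contributions_added_to_end_residues(self):
        p = sequence_charge_profile("GGG", 5.0, 9.0, TABLE, include_termini=True)
        n_ref = hh_charge("basic", TABLE.n_terminus, 5.0)
        n_int = hh_charge("basic", TABLE.n_terminus, 9.0)
        c_ref = hh_charge("acidic", TABLE.c_terminus, 5.0)
        assert p.residues[0].charge_ref == pytest.approx(n_ref, abs=1e-12)
        assert p.residues[0].charge_int == pytest.approx(n_int, abs=1e-12)
        assert p.residues[1].charge_ref == 0.0  # middle residue untouched
        assert p.residues[2].charge_ref == pytest.approx(c_ref, abs=1e-12)

    def test_single_residue_gets_both_terminal_groups(self):
        p = sequence_charge_profile("G", 7.0, 7.0, TABLE, include_termini=True)
        expected = hh_charge("basic", TABLE.n_terminus, 7.0) + \
            hh_charge("acidic", TABLE.c_terminus, 7.0)
        assert p.residues[0].charge_ref == pytest.approx(expected, abs=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(SequenceError):
            sequence_charge_profile("  \n ", 7.0, 5.0, TABLE)

    def test_raising_ph_gives_non_positive_score(self):
        p = sequence_charge_profile("DEKRHCY", 4.0, 10.0, TABLE)
        assert overall_charge_score(p) <= 0.0

    @given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30),
           ph_a=st.floats(min_value=0.5, max_value=13.5),
           ph_b=st.floats(min_value=0.5, max_value=13.5))
    @settings(max_examples=100, deadline=None)
    def test_score_swap_antisymmetry_and_naive_normalization(self, seq, ph_a, ph_b):
        p = sequence_charge_profile(seq, ph_a, ph_b, TABLE)
        q = sequence_charge_profile(seq, ph_b, ph_a, TABLE)
        assert p.overall_charge_score == pytest.approx(
            -q.overall_charge_score, abs=1e-12)
        # oracle: score equals the plain mean of per-residue deltas
        naive = sum(r.delta for r in p.residues) / len(p.residues)
        assert p.overall_charge_score == pytest.approx(naive, abs=1e-9)

    @given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=20))
    @settings(max_examples=60, deadline=None)
    def test_total_charge_non_increasing_in_ph(self, seq):
        grid = [1.0, 3.0, 5.0, 7.0, 9.0, 11.0, 13.0]
        totals = []
        for ph in grid:
            p = sequence_charge_profile(seq, ph, ph, TABLE, include_termini=True)
            totals.append(sum(r.charge_ref for r in p.residues))
        assert all(a >= b - 1e-12 for a, b in zip(totals, totals[1:]))


class TestPhScanRank:
    def test_ionizable_sequence_outranks_inert_one(self):
        result = ph_scan_rank([("g", "GGGG"), ("d", "DDDD")])
        assert [e.sequence_id for e in result.entries] == ["d", "g"]
        assert result.entries[0].rank == 1
        assert len(result.entries[0].shift_scores) == 13  # grid length - 1

    def test_single_record_gets_rank_one(self):
        result = ph_scan_rank([("only", "GGG")])
        assert result.entries[0].rank == 1

    def test_duplicate_sequences_tie_broken_by_id(self):
        result = ph_scan_rank([("b", "DDDD"), ("a", "DDDD")])
        assert result.entries[0].mean_score == result.entries[1].mean_score
        assert [e.sequence_id for e in result.entries] == ["a", "b"]

    def test_permutation_invariance(self):
        records = [("a", "DDDD"), ("b", "KKKK"), ("c", "GGGG"), ("d", "HHH")]
        fwd = ph_scan_rank(records)
        rev = ph_scan_rank(records[::-1])
        assert [e.sequence_id for e in fwd.entries] == \
            [e.sequence_id for e in rev.entries]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(SequenceError):
            ph_scan_rank([("x", "GG"), ("x", "DD")])

    def test_invalid_record_skipped_and_reported(self):
        result = ph_scan_rank([("ok", "DDDD"), ("bad", "D#D")])
        assert [e.sequence_id for e in result.entries] == ["ok"]
        assert result.skipped[0][0] == "bad"

    def test_record_cap_enforced(self):
        records = [(f"s{i}", "GG") for i in range(5)]
        with pytest.raises(SequenceError):
            ph_scan_rank(records, record_cap=3)
        assert ph_scan_rank(records, record_cap=None).entries

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(ValueError):
            ph_scan_rank([("a", "GG")], grid=[7.0, 7.0])

    def test_mean_score_is_mean_of_shift_scores(self):
        result = ph_scan_rank([("d", "DDDD")], grid=[3.0, 4.0, 5.0])
        entry = result.entries[0]
        assert entry.mean_score == pytest.approx(
            math.fsum(entry.shift_scores) / len(entry.shift_scores), abs=1e-12)


def test_pka_table_validation():
    with pytest.raises(ValueError):
        PkaTable(side_chain={"D": 15.0})
    with pytest.raises(ValueError):
        PkaTable(side_chain={"G": 7.0})
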