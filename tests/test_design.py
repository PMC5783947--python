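"""Library enumeration, counting formulas, probe sequences, names, layout."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acescan.aptamer import AptamerConstruct, CoordinateError
from acescan.design import (
    AceDesign,
    DesignError,
    assign_layout,
    count_perfect_match,
    count_single_mismatch,
    duplex_probe_core,
    end3,
    enumerate_perfect_match,
    enumerate_single_mismatch,
    format_name,
    is_degenerate,
    parse_name,
    probe_manifest,
    probe_sequence,
)

BASES = "ACGT"


def random_aptamer(length: int, seed: int = 0, ext: int = 0) -> AptamerConstruct:
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(BASES), length))
    return AptamerConstruct(id=f"rand{length}", sequence=seq, consensus_start=ext + 1)


def brute_force_pm(L: int, X: int, Y: int) -> int:
    seq = "A" * L
    return sum(
        len([seq[i : i + n] for i in range(L - n + 1)]) for n in range(X, Y + 1)
    )


def brute_force_mm(L: int, X: int, Y: int) -> int:
    return sum(
        sum(1 for _ in range(n)) * (L - n + 1) for n in range(X, Y + 1)
    )


class TestCoordinates:
    def test_extension_coordinates_skip_zero(self, atp_aptamer):
        assert atp_aptamer.first_coord == -5
        assert atp_aptamer.last_coord == 27
        assert atp_aptamer.base(-5) == "C"
        assert atp_aptamer.base(-2) == "T"
        assert atp_aptamer.base(1) == "A"
        with pytest.raises(CoordinateError):
            atp_aptamer.base(0)
        assert atp_aptamer.shift(-1, 1) == 1
        assert atp_aptamer.shift(1, -1) == -1

    def test_alphabet_validation(self):
        with pytest.raises(ValueError):
            AptamerConstruct("bad", "ACGTU")  # mixed T and U
        assert AptamerConstruct("rna", "ACGU").alphabet == "RNA"


class TestCounting:
    @pytest.mark.parametrize(
        "L,X,Y,expected",
        [(32, 7, 12, 141), (10, 1, 10, 55), (5, 5, 5, 1), (32, 7, 32, 351)],
    )
    def test_perfect_match_spot_checks(self, L, X, Y, expected):
        assert count_perfect_match(L, X, Y) == expected
        assert count_perfect_match(L, X, Y) == brute_force_pm(L, X, Y)

    @pytest.mark.parametrize(
        "L,X,Y,expected", [(32, 12, 12, 252), (32, 15, 15, 270), (4, 1, 1, 4)]
    )
    def test_single_mismatch_spot_checks(self, L, X, Y, expected):
        assert count_single_mismatch(L, X, Y) == expected
        assert count_single_mismatch(L, X, Y) == brute_force_mm(L, X, Y)

    @given(
        st.integers(1, 40).flatmap(
            lambda L: st.tuples(
                st.just(L), st.integers(1, L), st.integers(1, L)
            )
        )
    )
    def test_closed_forms_match_brute_force(self, LXY):
        L, a, b = LXY
        X, Y = min(a, b), max(a, b)
        assert count_perfect_match(L, X, Y) == brute_force_pm(L, X, Y)
        assert count_single_mismatch(L, X, Y) == brute_force_mm(L, X, Y)

    def test_single_length_specializations(self):
        for L in (10, 32):
            for N in range(1, L + 1):
                assert count_perfect_match(L, N, N) == L - N + 1
                assert count_single_mismatch(L, N, N) == N * (L - N + 1)

    def test_invalid_bounds(self):
        with pytest.raises(DesignError):
            count_perfect_match(10, 5, 3)
        with pytest.raises(DesignError):
            count_single_mismatch(10, 0, 5)


class TestEnumeration:
    def test_counts_match_closed_forms(self, atp_aptamer):
        assert len(enumerate_perfect_match(atp_aptamer, 7, 7)) == 26
        assert len(enumerate_perfect_match(atp_aptamer, 32, 32)) == 1
        assert len(enumerate_perfect_match(atp_aptamer, 7, 12)) == 141
        assert len(enumerate_single_mismatch(atp_aptamer, [12])) == 252
        assert len(enumerate_single_mismatch(atp_aptamer, [12, 15])) == 252 + 270

    def test_no_duplicates(self, atp_aptamer):
        pm = enumerate_perfect_match(atp_aptamer, 7, 12)
        assert len({d.key for d in pm}) == len(pm)
        mm = enumerate_single_mismatch(atp_aptamer, [12])
        assert len({d.key for d in mm}) == len(mm)

    def test_length_exceeding_aptamer(self, atp_aptamer):
        with pytest.raises(DesignError, match="33"):
            enumerate_perfect_match(atp_aptamer, 7, 33)
        with pytest.raises(DesignError, match="40"):
            enumerate_single_mismatch(atp_aptamer, [40])


class TestProbes:
    def test_reverse_complement_with_spacer(self):
        apt = AptamerConstruct("x", "ACGT")
        probe = probe_sequence(AceDesign("x", 1, 4, spacer3_len=2), apt)
        assert probe == "ACGTTT"  # ACGT is self-reverse-complementary

    def test_rna_window_complemented_in_dna(self):
        apt = AptamerConstruct("r", "GGAU")
        assert probe_sequence(AceDesign("r", 1, 4, spacer3_len=0), apt) == "ATCC"

    def test_perfect_match_is_fully_complementary(self, atp_aptamer):
        for d in enumerate_perfect_match(atp_aptamer, 7, 9):
            core = duplex_probe_core(d, atp_aptamer)
            window = atp_aptamer.window_sequence(d.start5, d.length)
            pairs = zip(window, reversed(core))
            assert all(
                {a, b} in ({"A", "T"}, {"C", "G"}) for a, b in pairs
            )

    def test_mismatch_substitution_rule(self, atp_aptamer):
        # ACE opposite aptamer G carries A (A-G mismatch): coordinate 6 is G
        d = parse_name("5ʹ_4T:12:6G", atp_aptamer)
        core = duplex_probe_core(d, atp_aptamer)
        coords = atp_aptamer.window_coords(d.start5, d.length)
        j = d.length - 1 - coords.index(6)
        assert core[j] == "A"
        # and a probe base A (opposite aptamer T) becomes T (T-T mismatch)
        d2 = AceDesign("atp_dna", 4, 12, mismatch_pos=4)  # aptamer base 4 is T
        core2 = duplex_probe_core(d2, atp_aptamer)
        assert core2[-1] == "T"

    def test_exactly_one_position_differs(self, atp_aptamer):
        for d in enumerate_single_mismatch(atp_aptamer, [10]):
            pm = AceDesign(d.aptamer_id, d.start5, d.length)
            diffs = sum(
                a != b
                for a, b in zip(
                    duplex_probe_core(d, atp_aptamer),
                    duplex_probe_core(pm, atp_aptamer),
                )
            )
            assert diffs == (0 if is_degenerate(d, atp_aptamer) else 1)
            assert not is_degenerate(d, atp_aptamer)  # A/T rule has no fixed point

    def test_manifest_schema(self, atp_aptamer):
        man = probe_manifest(enumerate_perfect_match(atp_aptamer, 7, 8), atp_aptamer)
        assert len(man) == 26 + 25
        assert man["probe_sequence"].str.len().eq(man["length"] + 25).all()


class TestNames:
    @pytest.mark.parametrize(
        "name,start5,length,mm",
        [
            ("5ʹ_1A:11", 1, 11, None),
            ("3ʹ_11G:11", 1, 11, None),
            ("5ʹ_-5C:9", -5, 9, None),
            ("5ʹQ_-5C:9", -5, 9, None),
            ("5ʹ_4T:12:6G", 4, 12, 6),
        ],
    )
    def test_parse_worked_examples(self, atp_aptamer, name, start5, length, mm):
        d = parse_name(name, atp_aptamer)
        assert (d.start5, d.length, d.mismatch_pos) == (start5, length, mm)

    def test_anchor_conversion(self, atp_aptamer):
        d = parse_name("5ʹ_1A:11", atp_aptamer)
        assert end3(d, atp_aptamer) == 11
        assert format_name(d, atp_aptamer, "3p") == "3ʹ_11G:11"
        # a window crossing the consensus boundary skips coordinate 0
        d2 = parse_name("5ʹ_-5C:15", atp_aptamer)
        assert end3(d2, atp_aptamer) == 10

    def test_round_trip_on_all_designs(self, atp_aptamer):
        designs = enumerate_perfect_match(atp_aptamer, 7, 12)
        designs += enumerate_single_mismatch(atp_aptamer, [12])
        for d in designs:
            for anchor in ("5p", "3p"):
                back = parse_name(format_name(d, atp_aptamer, anchor), atp_aptamer)
                assert back.key == d.key

    def test_base_letter_validation(self, atp_aptamer):
        with pytest.raises(DesignError, match="coordinate 1"):
            parse_name("5ʹ_1C:11", atp_aptamer)  # base 1 is A, not C
        with pytest.raises(DesignError, match="malformed"):
            parse_name("hello", atp_aptamer)


class TestLayout:
    def test_determinism_and_seed_sensitivity(self, atp_aptamer):
        designs = enumerate_perfect_match(atp_aptamer, 7, 9)
        a = assign_layout(designs, atp_aptamer, 6, 5, seed=1)
        b = assign_layout(designs, atp_aptamer, 6, 5, seed=1)
        c = assign_layout(designs, atp_aptamer, 6, 5, seed=2)
        assert a.assignment.equals(b.assignment)
        assert not a.assignment.equals(c.assignment)
        # identical multiset of placements regardless of seed
        key = ["ace_id", "replicate"]
        assert (
            a.assignment[key].sort_values(key).reset_index(drop=True).equals(
                c.assignment[key].sort_values(key).reset_index(drop=True)
            )
        )

    def test_capacity(self, atp_aptamer):
        designs = enumerate_perfect_match(atp_aptamer, 7, 9)
        with pytest.raises(DesignError, match="required"):
            assign_layout(designs, atp_aptamer, 6, 5, seed=0, grid=(5, 5))
        # 1400 ACEs x 5 replicates exactly fill a 7000-spot sub-array
        assert 1400 * 5 == 7000

    def test_every_design_replicated(self, atp_aptamer):
        designs = enumerate_perfect_match(atp_aptamer, 10, 12)
        lay = assign_layout(designs, atp_aptamer, 3, 4, seed=9)
        counts = lay.assignment.groupby("ace_id").size()
        assert (counts == 4).all() and len(counts) == len(designs)
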