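"""Secondary-structure grammar: parsing, validation, moves and pathways."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from stepstone.sspath import (
    SS_1PGB,
    SS_2GYC,
    PathDeadEndError,
    build_path,
    enumerate_moves,
    enumerate_pathways,
    is_valid,
    parse_elements,
    ss_distance,
    validate,
)


class TestParseElements:
    @pytest.mark.parametrize(
        "ss, kinds, lengths",
        [
            (SS_1PGB, "EEHEE", [7, 7, 15, 5, 5]),
            (SS_2GYC, "EHEHE", [5, 8, 4, 7, 2]),
            ("C" * 30, "", []),
            ("HHHHCEE", "HE", [4, 2]),
        ],
    )
    def test_kinds_and_lengths(self, ss, kinds, lengths):
        els = parse_elements(ss)
        assert "".join(e.kind for e in els) == kinds
        assert [e.length for e in els] == lengths

    def test_elements_ordered_and_disjoint(self):
        els = parse_elements(SS_1PGB)
        for a, b in zip(els, els[1:]):
            assert a.end <= b.start

    def test_bad_character_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            parse_elements("HHHX")


class TestValidate:
    def test_endpoints_valid(self):
        assert validate(SS_1PGB) == []
        assert validate(SS_2GYC) == []

    def test_overlong_helix_flagged(self):
        # 16-long helix, total kept in range by extra strands
        ss = "C" + "H" * 16 + "C" + "E" * 8 + "C" + "E" * 8 + "C" * 10
        rules = {v.rule for v in validate(ss)}
        assert "element-length" in rules

    def test_touching_runs_flagged(self):
        ss = "C" + "E" * 8 + "H" * 12 + "C" + "E" * 8 + "C" * 10
        rules = {v.rule for v in validate(ss)}
        assert "separation" in rules

    @pytest.mark.parametrize(
        "n_structured, ok", [(19, False), (20, True), (45, True), (46, False)]
    )
    def test_total_structured_bounds(self, n_structured, ok):
        # build from length-5 strands (and one remainder run) separated by coils
        runs = []
        left = n_structured
        while left > 0:
            take = min(5, left)
            if take == 1:  # avoid sub-minimal strand
                runs[-1] = "E" * 6
            else:
                runs.append("E" * take)
            left -= take
        ss = "C" + "C".join(runs) + "C"
        ss += "C" * (80 - len(ss))
        assert sum(c != "C" for c in ss) == n_structured
        assert is_valid(ss) is ok


class TestMoves:
    def test_helix_insertion_offered_in_wide_coil_window(self):
        ss = "C" + "E" * 7 + "CCCCCCCC" + "E" * 7 + "C" + "E" * 7 + "C" * 10
        moves = enumerate_moves(ss)
        assert any(m.kind == "insert" and m.element_kind == "H" for m, _ in moves)

    def test_no_growth_moves_at_structured_ceiling(self):
        # 45 structured residues: lengthen and insert all violate the cap
        ss = ("C" + "E" * 8) * 5 + "C" + "H" * 5 + "C" * 8
        assert sum(c != "C" for c in ss) == 45
        assert is_valid(ss)
        kinds = {m.kind for m, _ in enumerate_moves(ss)}
        assert "lengthen" not in kinds
        assert "insert" not in kinds

    def test_minimal_strand_deleted_not_shortened(self):
        ss = "C" + "E" * 8 + "C" + "EE" + "C" + "E" * 8 + "CC" + "E" * 8 + "C" * 10
        moves = enumerate_moves(ss)
        strand2 = [(m, s) for m, s in moves if m.position in (10, 11)]
        assert any(m.kind == "delete" for m, _ in strand2)
        assert not any(m.kind == "shorten" for m, _ in strand2)

    def test_all_results_revalidate(self):
        for _, s in enumerate_moves(SS_1PGB):
            assert is_valid(s)

    def test_invalid_input_rejected_with_report(self):
        with pytest.raises(ValueError, match="invalid SS string"):
            enumerate_moves("C" * 5 + "H" * 20 + "C" * 5)

    def test_targeted_moves_strictly_decrease_distance(self):
        d0 = ss_distance(SS_1PGB, SS_2GYC)
        for _, s in enumerate_moves(SS_1PGB, target=SS_2GYC):
            assert ss_distance(s, SS_2GYC) < d0


def _exhaustive_matchings(src, dst):
    """Brute-force oracle: filter all subsets of the pair product."""
    import itertools

    pairs = [
        (i, j)
        for i in range(len(src))
        for j in range(len(dst))
        if src[i] == dst[j]
    ]
    found = set()
    for r in range(len(pairs) + 1):
        for combo in itertools.combinations(pairs, r):
            srcs = [i for i, _ in combo]
            dsts = [j for _, j in combo]
            if len(set(srcs)) < len(srcs) or len(set(dsts)) < len(dsts):
                continue
            if sorted(combo) != sorted(combo, key=lambda p: (p[0], p[1])):
                continue
            ordered = sorted(combo)
            if any(b[1] <= a[1] for a, b in zip(ordered, ordered[1:])):
                continue
            found.add(frozenset(combo))
    return found


class TestPathways:
    def test_endpoint_pathway_count_is_seven(self):
        assert len(enumerate_pathways(SS_1PGB, SS_2GYC)) == 7

    def test_matchings_agree_with_exhaustive_oracle(self):
        maps = enumerate_pathways(SS_1PGB, SS_2GYC)
        got = {frozenset((i - 1, j - 1) for i, j in m.pairs) for m in maps}
        assert got == _exhaustive_matchings("EHE", "HEH")

    @pytest.mark.parametrize(
        "src_internal, dst_internal, expected",
        [("H", "E", 1), ("H", "H", 2), ("", "HEH", 1), ("HE", "HE", 4)],
    )
    def test_small_cases_match_oracle(self, src_internal, dst_internal, expected):
        pad = "C" * 10
        src = pad + "EEE" + pad + "C".join(
            ("HHHH" if c == "H" else "EEE") for c in src_internal
        ) + pad + "EEE" + pad
        dst = pad + "EEE" + pad + "C".join(
            ("HHHH" if c == "H" else "EEE") for c in dst_internal
        ) + pad + "EEE" + pad
        n = max(len(src), len(dst))
        src, dst = src.ljust(n, "C"), dst.ljust(n, "C")
        maps = enumerate_pathways(src, dst)
        assert len(maps) == expected
        assert len(maps) == len(_exhaustive_matchings(src_internal, dst_internal))

    def test_reversal_symmetry(self):
        fwd = enumerate_pathways(SS_1PGB, SS_2GYC)
        rev = enumerate_pathways(SS_2GYC, SS_1PGB)
        assert len(fwd) == len(rev)

    def test_missing_terminal_strand_rejected(self):
        ss = "C" * 10 + "H" * 10 + "C" + "E" * 10 + "C" * 10
        with pytest.raises(ValueError, match="terminal"):
            enumerate_pathways(ss, SS_2GYC)


class TestBuildPath:
    def test_identity_path_is_empty(self):
        path = build_path(SS_1PGB, SS_1PGB)
        assert len(path) == 0
        assert path.states == [SS_1PGB]

    def test_single_move_path(self):
        moves = enumerate_moves(SS_1PGB)
        _, one_away = moves[0]
        path = build_path(SS_1PGB, one_away)
        assert len(path) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_endpoint_path_is_legal_and_monotone(self, seed):
        mapping = enumerate_pathways(SS_1PGB, SS_2GYC)[0]
        path = build_path(SS_1PGB, SS_2GYC, mapping, rng_seed=seed)
        assert path.states[0] == SS_1PGB
        assert path.states[-1] == SS_2GYC
        for prev, cur in zip(path.states, path.states[1:]):
            assert is_valid(cur)
            # exactly one legal move apart
            assert cur in {s for _, s in enumerate_moves(prev)}
        assert all(b < a for a, b in zip(path.distances, path.distances[1:]))

    def test_deterministic_given_seed(self):
        p1 = build_path(SS_1PGB, SS_2GYC, rng_seed=3)
        p2 = build_path(SS_1PGB, SS_2GYC, rng_seed=3)
        assert p1.states == p2.states

    def test_length_bounded_by_initial_distance(self):
        path = build_path(SS_1PGB, SS_2GYC, rng_seed=0)
        assert len(path) <= ss_distance(SS_1PGB, SS_2GYC)


@settings(max_examples=25, deadline=None)
@given(hst.integers(min_value=0, max_value=10_000))
def test_random_move_sequences_stay_valid(seed):
    """Random walks through the move graph never leave the legal set."""
    rng = np.random.default_rng(seed)
    ss = SS_1PGB
    for _ in range(5):
        options = enumerate_moves(ss)
        if not options:
            break
        _, ss = options[rng.integers(len(options))]
        assert is_valid(ss)
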