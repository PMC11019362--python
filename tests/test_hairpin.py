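"""Hairpin-loop search, nearest-neighbor delta-G, and the didymi loop motif.

The brute-force oracle below re-enumerates every (loop, stem, defect)
configuration recursively and scores it with its own walk over the shipped
parameter table, independently of the package's search.
"""

import numpy as np
import pytest

from apohm.hairpin import (
    HairpinStructure,
    ThermoParams,
    best_hairpin_in_window,
    default_params,
    find_best_hairpin,
    hairpin_delta_g,
    loop_pattern_flag,
)
from apohm.io import revcomp

WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


# --- independent oracle ----------------------------------------------------

def oracle_score(w, ls, le, events, params):
    dg = params.loop_table.get(le - ls)
    if dg is None:
        raise AssertionError("oracle only scores tabulated loop sizes")
    if le - ls <= 4:
        dg += params.special_loops.get(w[ls - 1] + w[ls:le] + w[le], 0.0)
    pairs = []  # (i, j, separated_by) accumulated inner->outer
    sep = "adjacent"
    for ev in events:
        if ev[0] == "pair":
            pairs.append((ev[1], ev[2], sep))
            sep = "adjacent"
        elif ev[0] == "mismatch":
            dg += params.mismatch_penalty
            sep = "mismatch"
        else:
            sep = "bulge"
    for (i1, j1, _), (i2, j2, sep) in zip(pairs, pairs[1:]):
        if sep == "mismatch":
            continue
        if sep == "bulge":
            dg += params.bulge_penalty
        dg += params.stacks[f"{w[i2]}{w[i1]}/{w[j2]}{w[j1]}"]
    return dg


def oracle_stems(w, i, j, defect_used):
    """Yield all stem continuations (lists of events) from (i, j) outward."""
    n = len(w)
    if i >= 0 and j < n and (w[i], w[j]) in WC:
        yield [("pair", i, j)]
        for rest in oracle_stems(w, i - 1, j + 1, defect_used):
            yield [("pair", i, j)] + rest
    if not defect_used:
        if i >= 0 and j < n and (w[i], w[j]) not in WC and w[i] in "ACGT" and w[j] in "ACGT":
            for rest in oracle_stems(w, i - 1, j + 1, True):
                yield [("mismatch", i, j)] + rest
        if i >= 0:
            for rest in oracle_stems(w, i - 1, j, True):
                yield [("bulge", "left", i)] + rest
        if j < n:
            for rest in oracle_stems(w, i, j + 1, True):
                yield [("bulge", "right", j)] + rest


def oracle_min_dg(w, center, params, min_loop=3, max_loop=10, min_stem=2):
    best = None
    n = len(w)
    for size in range(min_loop, max_loop + 1):
        for ls in range(max(1, center - size + 1), center + 1):
            le = ls + size
            if le > n - 1 or not (ls <= center < le):
                continue
            if (w[ls - 1], w[le]) not in WC:
                continue
            for stem in oracle_stems(w, ls - 2, le + 1, False):
                if stem[-1][0] != "pair":
                    continue  # defects are internal, never terminal
                matched = 1 + sum(1 for ev in stem if ev[0] == "pair")
                if matched < min_stem:
                    continue
                events = [("pair", ls - 1, le)] + stem
                dg = oracle_score(w, ls, le, events, params)
                if best is None or dg < best:
                    best = dg
    return best


def random_windows(n_windows, length=41, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n_windows):
        yield "".join(rng.choice(list("ACGT"), size=length))


# --- tests -----------------------------------------------------------------

class TestSearch:
    def test_constructed_palindrome(self):
        w = "AAAAGCCGTTTCGGCAAAA"
        hp = best_hairpin_in_window(w, 10)  # center in the TTT loop
        assert hp.loop_seq == "TTT"
        assert hp.stem_len == 4
        assert hp.defect is None

    def test_poly_a_has_no_structure(self):
        assert best_hairpin_in_window("A" * 41, 20) is None

    def test_agrees_with_enumeration_oracle(self):
        params = default_params()
        n_checked = 0
        for w in random_windows(150, seed=42):
            hp = best_hairpin_in_window(w, 20)
            expect = oracle_min_dg(w, 20, params)
            if expect is None:
                assert hp is None
            else:
                assert hp is not None
                assert hp.delta_g == pytest.approx(expect, abs=1e-9)
                n_checked += 1
        assert n_checked > 50

    def test_strand_symmetry(self):
        for w in random_windows(60, seed=7):
            hp_f = best_hairpin_in_window(w, 20)
            hp_r = best_hairpin_in_window(revcomp(w), 20)
            if hp_f is None:
                assert hp_r is None
            else:
                assert hp_r.delta_g == pytest.approx(hp_f.delta_g, abs=1e-9)

    def test_deterministic_tie_breaking(self):
        for w in random_windows(25, seed=5):
            a = best_hairpin_in_window(w, 20)
            b = best_hairpin_in_window(w, 20)
            assert (a is None and b is None) or (
                a.events == b.events and a.loop_start == b.loop_start
            )

    def test_structure_invariants(self):
        for w in random_windows(80, seed=9):
            hp = best_hairpin_in_window(w, 20)
            if hp is None:
                continue
            assert 3 <= hp.loop_size <= 10
            assert hp.loop_start <= 20 < hp.loop_end
            assert 0 <= hp.mut_loop_index < hp.loop_size
            assert hp.stem_len >= 2
            n_defects = sum(1 for ev in hp.events if ev[0] != "pair")
            assert n_defects <= 1
            assert hp.events[0][0] == "pair" and hp.events[-1][0] == "pair"
            for ev in hp.events:
                if ev[0] == "pair":
                    assert (w[ev[1]], w[ev[2]]) in WC


class TestDeltaG:
    def test_hand_sum_two_gc_pairs_aaaa_loop(self):
        # window GGAAAACC: closing pair (1,6), outer pair (0,7), loop AAAA
        params = default_params()
        hp = HairpinStructure(
            window="GGAAAACC", loop_start=2, loop_end=6, stem_len=2,
            events=(("pair", 1, 6), ("pair", 0, 7)), defect=None,
            delta_g=0.0, mut_loop_index=1,
        )
        expected = params.stacks["GG/CC"] + params.loop_table[4]
        expected += params.special_loops.get("GAAAAC", 0.0)
        assert hairpin_delta_g(hp) == pytest.approx(expected)

    def test_pure_function(self):
        w = "AAAAGCCGTTTCGGCAAAA"
        hp = best_hairpin_in_window(w, 10)
        assert hairpin_delta_g(hp) == pytest.approx(hp.delta_g)

    def test_extending_perfect_stem_never_destabilizes(self):
        """With all stack terms negative, adding a complementary pair to a
        perfect stem cannot raise delta-G (checked against enumeration)."""
        params = default_params()
        rng = np.random.default_rng(13)
        for _ in range(40):
            arm = "".join(rng.choice(list("ACGT"), size=6))
            loop = "".join(rng.choice(list("ACGT"), size=4))
            w = "T" + arm + loop + revcomp(arm) + "T"
            center = 1 + len(arm) + 1
            hp = best_hairpin_in_window(w, center)
            assert hp is not None
            # the planted full-stem structure is at least as stable as any
            # shorter prefix of the same stem
            prefix_events = hp.events[: max(2, len(hp.events) - 1)]
            if all(ev[0] == "pair" for ev in hp.events) and len(prefix_events) >= 2:
                shorter = HairpinStructure(
                    window=w, loop_start=hp.loop_start, loop_end=hp.loop_end,
                    stem_len=len(prefix_events), events=tuple(prefix_events),
                    defect=None, delta_g=0.0, mut_loop_index=hp.mut_loop_index,
                )
                assert hp.delta_g <= hairpin_delta_g(shorter) + 1e-12

    def test_non_acgt_rejected(self):
        hp = HairpinStructure(
            window="GGANAACC", loop_start=2, loop_end=6, stem_len=2,
            events=(("pair", 1, 6), ("pair", 0, 7)), defect=None,
            delta_g=0.0, mut_loop_index=1,
        )
        with pytest.raises(ValueError):
            hairpin_delta_g(hp)


class TestFindBestHairpinGenomic:
    def test_planted_hairpin_found(self, reference):
        from conftest import DIDYMI_POS_A, DIDYMI_POS_B, HAIRPIN_LOOP

        hp = find_best_hairpin(reference, "chrHp", DIDYMI_POS_A)
        assert hp is not None
        assert hp.loop_seq == HAIRPIN_LOOP
        assert hp.delta_g < 0
        assert hp.loop_gstart <= DIDYMI_POS_A <= hp.loop_gend
        assert hp.loop_gstart <= DIDYMI_POS_B <= hp.loop_gend

    def test_purine_site_is_strand_normalized(self, reference, contigs):
        from conftest import DIDYMI_POS_A

        # the G pairing the loop-adjacent base on the opposite strand:
        # use the complementary strand position of the TpC cytosine itself
        seq = contigs["chrHp"]
        assert seq[DIDYMI_POS_A - 1] == "C"
        # interrogating a G elsewhere must flip and still return a structure
        g_pos = next(
            i + 1 for i, b in enumerate(seq) if b == "G" and 60 < i < 120
        )
        hp = find_best_hairpin(reference, "chrHp", g_pos)
        if hp is not None:
            assert hp.strand_flipped

    def test_contig_end_returns_none(self, reference):
        assert find_best_hairpin(reference, "chrHp", 3) is None

    def test_window_truncation_uses_flank(self, contigs):
        ref = {"c": contigs["chrHp"]}
        assert find_best_hairpin(ref, "c", 30, flank=50) is None


class TestLoopPatternFlag:
    @pytest.mark.parametrize(
        "loop,mutated,expected",
        [
            ("TCAAC", {1, 4}, True),   # C-A-A-C is 1001 with mutated ends
            ("TCGC", {1}, False),      # middle base G breaks the 0-run
            ("TAAAC", {4}, False),     # three A/T between: spacing too wide
            ("TCAC", {1}, True),       # C-A-C is 101
            ("TCAC", {2}, False),      # mutated base not at a terminal 1
            ("GAAG", {0}, True),
        ],
    )
    def test_motif_truth_table(self, loop, mutated, expected):
        assert loop_pattern_flag(loop, mutated) is expected
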