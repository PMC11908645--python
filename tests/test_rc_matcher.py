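import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgcodec.io_fastq import reverse_complement
from pgcodec.rc_matcher import (RcCorruptionError, RcMatch, RcParams,
                                apply_rc_matches, find_rc_matches,
                                undo_rc_matches)

from _oracles import brute_rc_runs, covers_planted_repeat

SMALL = RcParams(min_rc_match=12, rc_k=8, rc_step=4)


def _random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestFindRcMatches:
    def test_planted_full_copy(self):
        rng = random.Random(1)
        s = _random_dna(rng, 200)
        matches = find_rc_matches(s + reverse_complement(s), RcParams())
        assert len(matches) == 1
        m = matches[0]
        assert (m.src_start, m.dest_start, m.length) == (0, 200, 200)

    def test_random_text_has_no_long_rc_repeat(self):
        rng = random.Random(2)
        text = _random_dna(rng, 500)
        assert brute_rc_runs(text, 48) == []  # oracle confirms none exist
        assert find_rc_matches(text, RcParams()) == []

    def test_substitution_splits_planted_copy(self):
        rng = random.Random(3)
        s = _random_dna(rng, 200)
        copy = list(reverse_complement(s))
        copy[100] = "A" if copy[100] != "A" else "C"
        text = s + "".join(copy)
        matches = find_rc_matches(text, RcParams())
        oracle = brute_rc_runs(text, RcParams().min_rc_match)
        assert matches  # the exact runs either side still qualify
        for m in matches:
            assert any(m.length <= length for _, _, length in oracle)

    @pytest.mark.parametrize("seed", range(5))
    def test_all_reported_matches_are_genuine(self, seed):
        rng = random.Random(100 + seed)
        pieces = [_random_dna(rng, rng.randint(30, 80)) for _ in range(4)]
        text = (pieces[0] + pieces[1] + reverse_complement(pieces[1])
                + pieces[2] + reverse_complement(pieces[0]) + pieces[3])
        matches = find_rc_matches(text, SMALL)
        for m in matches:
            assert m.dest_start > m.src_start
            assert m.src_start + m.length <= m.dest_start
            assert m.length >= SMALL.min_rc_match
            assert reverse_complement(
                text[m.src_start:m.src_start + m.length]
            ) == text[m.dest_start:m.dest_start + m.length]

    def test_planted_repeat_is_covered(self):
        rng = random.Random(7)
        left = _random_dna(rng, 80)
        s = _random_dna(rng, 60)
        mid = _random_dna(rng, 50)
        text = left + s + mid + reverse_complement(s)
        matches = find_rc_matches(text, SMALL)
        assert covers_planted_repeat(matches, 80, 80 + 60 + 50, 60)

    def test_param_guarantee_constraint_enforced(self):
        with pytest.raises(ValueError):
            RcParams(min_rc_match=10, rc_k=8, rc_step=4)


class TestApplyUndo:
    def test_worked_example(self):
        residual, srcs, lens = apply_rc_matches(
            "AAAATTTT", [RcMatch(4, 0, 4)])
        assert (residual, srcs, lens) == ("AAAA%", [0], [4])
        assert undo_rc_matches(residual, srcs, lens) == "AAAATTTT"

    def test_empty_match_list_is_identity(self):
        residual, srcs, lens = apply_rc_matches("ACGTACGT", [])
        assert residual == "ACGTACGT" and not srcs and not lens
        assert undo_rc_matches(residual, srcs, lens) == "ACGTACGT"

    def test_overlapping_matches_rejected(self):
        with pytest.raises(ValueError):
            apply_rc_matches("A" * 20, [RcMatch(4, 0, 4), RcMatch(6, 0, 4)])

    def test_sentinel_stream_count_mismatch(self):
        with pytest.raises(RcCorruptionError):
            undo_rc_matches("AAA%", [0, 1], [4, 4])

    def test_nested_reconstruction(self):
        """A later match whose source lies inside the first match's expansion."""
        rng = random.Random(9)
        a = _random_dna(rng, 40)
        text = a + reverse_complement(a) + a  # 3rd block = rc of 2nd block
        params = RcParams(min_rc_match=16, rc_k=8, rc_step=4)
        matches = find_rc_matches(text, params)
        residual, srcs, lens = apply_rc_matches(text, matches)
        assert len(matches) == 2
        assert matches[1].src_start >= matches[0].dest_start  # source in excised region
        assert undo_rc_matches(residual, srcs, lens) == text

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_undo_inverts_apply_on_planted_repeats(self, data):
        rng = random.Random(data.draw(st.integers(0, 10_000)))
        chunks = []
        planted = []
        pos = 0
        for _ in range(rng.randint(1, 3)):
            filler = _random_dna(rng, rng.randint(20, 60))
            s = _random_dna(rng, rng.randint(16, 40))
            chunks += [filler, s, _random_dna(rng, rng.randint(10, 30)),
                       reverse_complement(s)]
        text = "".join(chunks)
        matches = find_rc_matches(text, SMALL)
        residual, srcs, lens = apply_rc_matches(text, matches)
        assert undo_rc_matches(residual, srcs, lens) == text
        if matches:
            assert residual.count("%") == len(matches)
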