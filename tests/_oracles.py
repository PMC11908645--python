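"""Independent brute-force oracles used by the test suite."""

from __future__ import annotations

from itertools import permutations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def _merge(a: str, b: str) -> str:
    """Append b to a using their maximal suffix-prefix overlap."""
    if b in a:
        return a
    for ov in range(min(len(a), len(b)), 0, -1):
        if a.endswith(b[:ov]):
            return a + b[ov:]
    return a + b


def brute_scs_length(seqs: list[str]) -> int:
    """Exact minimum common superstring length by exhaustive ordering.

    Contained strings are dropped first; the optimum is then the best
    max-overlap merge over all permutations.
    """
    kept = [s for i, s in enumerate(seqs)
            if not any(s in t for j, t in enumerate(seqs) if i != j
                       or (s == t and j < i))]
    # keep one copy of duplicates
    uniq: list[str] = []
    for s in kept:
        if s not in uniq:
            uniq.append(s)
    if not uniq:
        return 0
    best = None
    for perm in permutations(uniq):
        cur = perm[0]
        for nxt in perm[1:]:
            cur = _merge(cur, nxt)
        if best is None or len(cur) < len(best):
            best = cur
    for s in seqs:
        assert s in best
    return len(best)


def brute_rc_runs(text: str, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal reverse-complement repeat runs of length >= min_len.

    A run lives on an anti-diagonal s = src_i + dest_j of the complement
    match matrix (text[i] == comp(text[s-i])); the relation is symmetric in
    i <-> s-i, so each run is reported once with the source strictly before
    the destination (src_end <= dest_start), clipping palindromic runs at
    the diagonal centre. Returns (src_start, dest_start, length) triples.
    """
    n = len(text)
    runs = []
    for s in range(2 * n - 1):
        ilo, ihi = max(0, s - n + 1), min(n - 1, s)
        i = ilo
        while i <= ihi:
            if text[i] != _COMP.get(text[s - i], "?"):
                i += 1
                continue
            a = i
            while i + 1 <= ihi and text[i + 1] == _COMP.get(text[s - i - 1], "?"):
                i += 1
            b = i
            i += 1
            if a > (s - 1) // 2:
                continue  # mirror image of an already-reported run
            src_end = min(b, (s - 1) // 2)
            length = src_end - a + 1
            if length >= min_len:
                runs.append((a, s - src_end, length))
    return runs


def covers_planted_repeat(matches, src_start: int, dest_start: int,
                          length: int) -> bool:
    """Do the reported matches jointly cover a planted RC repeat region?"""
    covered = 0
    for m in matches:
        lo = max(m.dest_start, dest_start)
        hi = min(m.dest_start + m.length, dest_start + length)
        covered += max(0, hi - lo)
    return covered >= length
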