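"""Reverse-complement repeat removal inside the high-quality pseudogenome.

LZMA-class backends find forward repeats but are blind to reverse-complement
ones, so long RC repeats in PGhq are located with a canonical-k-mer hash
table over sparsely sampled positions and replaced by references: the later
occurrence is excised and marked with a single '%' sentinel in the residual
text, while its (source offset, length) pair goes to out-of-band streams.
The residual alphabet is {A, C, G, T, N, %}, which the variable-length
packer handles directly. The scan is sequential and deterministic; its
single-pass result is normative.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

from .io_fastq import reverse_complement

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "%": "%"}

SENTINEL = "%"


class RcCorruptionError(ValueError):
    """Sentinel count and match-stream length disagree."""


@dataclass(frozen=True)
class RcParams:
    min_rc_match: int = 48
    rc_k: int = 32
    rc_step: int = 16

    def __post_init__(self):
        if self.rc_k + self.rc_step - 1 > self.min_rc_match:
            raise ValueError(
                "need rc_k + rc_step - 1 <= min_rc_match for the detection "
                "guarantee"
            )


@dataclass(frozen=True)
class RcMatch:
    dest_start: int  # replaced (later) occurrence
    src_start: int   # retained (earlier) occurrence
    length: int


def find_rc_matches(text: str, params: RcParams | None = None) -> list[RcMatch]:
    """Greedy left-to-right scan for long reverse-complement repeats.

    A canonical-form k-mer table (key = lexicographic min of the k-mer and
    its reverse complement) indexes positions divisible by ``rc_step``; every
    scan position is probed, so any RC repeat of length >= ``min_rc_match``
    whose source copy contains a sampled k-mer is found. Hits are extended
    maximally in both directions under RC equality; accepted destination
    regions never overlap (first accepted wins), and a match's source region
    always ends before its destination starts, which guarantees the source
    is available during left-to-right reconstruction.
    """
    params = params or RcParams()
    k, step, min_len = params.rc_k, params.rc_step, params.min_rc_match
    n = len(text)
    if n < 2 * k:
        return []
    table: dict[str, list[int]] = defaultdict(list)
    for p in range(0, n - k + 1, step):
        km = text[p:p + k]
        if "N" in km or SENTINEL in km:
            continue
        table[min(km, reverse_complement(km))].append(p)

    matches: list[RcMatch] = []
    last_end = 0  # end of the last accepted destination region
    q = 0
    while q + k <= n:
        km = text[q:q + k]
        if "N" in km or SENTINEL in km:
            q += 1
            continue
        rkm = reverse_complement(km)
        accepted = False
        for p in table.get(min(km, rkm), ()):
            if p + k > q:  # source k-mer must lie strictly before the probe
                continue
            if text[p:p + k] != rkm:  # forward repeat, not RC
                continue
            # extend: src [sa, sb], dest [da, db]; pairing src i <-> dest s-i
            sa, sb = p, p + k - 1
            da, db = q, q + k - 1
            while (sa - 1 >= 0 and db + 1 < n
                   and text[sa - 1] == _COMP[text[db + 1]]):
                sa -= 1
                db += 1
            while (sb + 1 < da - 1 and da - 1 >= last_end
                   and text[sb + 1] == _COMP[text[da - 1]]):
                sb += 1
                da -= 1
            length = sb - sa + 1
            if length >= min_len and sb < da and da >= last_end:
                matches.append(RcMatch(da, sa, length))
                last_end = db + 1
                q = db + 1
                accepted = True
                break
        if not accepted:
            q += 1
    return matches


def apply_rc_matches(text: str, matches: Sequence[RcMatch]
                     ) -> tuple[str, list[int], list[int]]:
    """Excise destination regions, leaving one '%' sentinel per match.

    Matches must be sorted by ``dest_start`` and non-overlapping. Returns
    (residual text, source-offset stream, length stream) with the streams in
    sentinel order.
    """
    parts: list[str] = []
    srcs: list[int] = []
    lens: list[int] = []
    pos = 0
    for m in matches:
        if m.dest_start < pos:
            raise ValueError("overlapping or unsorted RC matches")
        parts.append(text[pos:m.dest_start])
        parts.append(SENTINEL)
        srcs.append(m.src_start)
        lens.append(m.length)
        pos = m.dest_start + m.length
    parts.append(text[pos:])
    return "".join(parts), srcs, lens


def undo_rc_matches(residual_text: str, srcs: Sequence[int],
                    lens: Sequence[int]) -> str:
    """Expand sentinels left-to-right against the already-rebuilt text."""
    if residual_text.count(SENTINEL) != len(srcs) or len(srcs) != len(lens):
        raise RcCorruptionError(
            f"sentinel count {residual_text.count(SENTINEL)} != "
            f"match stream length {len(srcs)}/{len(lens)}"
        )
    out: list[str] = []
    out_len = 0
    next_match = 0
    for chunk in residual_text.split(SENTINEL):
        out.append(chunk)
        out_len += len(chunk)
        if next_match < len(srcs):
            src, length = srcs[next_match], lens[next_match]
            next_match += 1
            if src + length > out_len:
                raise RcCorruptionError(
                    f"match {next_match - 1} source [{src}, {src + length}) "
                    f"not yet reconstructed (have {out_len})"
                )
            built = "".join(out)
            out = [built, reverse_complement(built[src:src + length])]
            out_len += length
    return "".join(out)
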