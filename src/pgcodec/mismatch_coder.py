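"""Rank coding of the mismatch-symbol stream.

Mismatched read symbols are replaced by their rank in the global order-0
frequency order of all mismatches (most frequent symbol gets rank 0), and the
rank is decreased by one whenever it lies above the rank of the pseudogenome
symbol at the same position — that symbol is excluded, since a mismatch can
never equal the reference. With a 5-symbol alphabet the emitted ranks fit in
[0, 3]. Context-free by design: order-0 statistics are enough here.

The rank table (a 5-symbol permutation) travels in the archive header; the
decoder never sees the raw mismatch symbols.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

#: tie-break order for equal counts (fixed so the table is deterministic)
_TIE_ORDER = "ACGNT"
#: fallback order for an empty mismatch stream
_FALLBACK = "ACGTN"
ALPHABET = frozenset("ACGTN")


class RankCorruptionError(ValueError):
    """A decoded rank lies outside the valid range."""


@dataclass(frozen=True)
class RankTable:
    order: str  # permutation of "ACGTN", most frequent mismatch first

    def __post_init__(self):
        if sorted(self.order) != sorted("ACGTN"):
            raise ValueError(f"order {self.order!r} is not a permutation of ACGTN")


def build_rank_table(mismatch_symbols: Iterable[str]) -> RankTable:
    """Order the 5 symbols by decreasing global mismatch count.

    Ties break by the fixed order A<C<G<N<T; an empty stream yields the
    fallback order (A, C, G, T, N).
    """
    counts = Counter(mismatch_symbols)
    if not counts:
        return RankTable(_FALLBACK)
    order = sorted("ACGTN", key=lambda s: (-counts.get(s, 0), _TIE_ORDER.index(s)))
    return RankTable("".join(order))


def rank_encode(mismatch: str, ref: str, table: RankTable) -> int:
    """Rank of ``mismatch`` with the reference symbol excluded."""
    if mismatch == ref:
        raise ValueError(f"mismatch symbol equals reference symbol {ref!r}")
    base = table.order.index(mismatch)
    if ref in table.order and base > table.order.index(ref):
        return base - 1
    return base


def rank_decode(rank: int, ref: str, table: RankTable) -> str:
    """Exact inverse of :func:`rank_encode`."""
    limit = 3 if ref in table.order else 4
    if not 0 <= rank <= limit:
        raise RankCorruptionError(f"rank {rank} out of range [0, {limit}]")
    if ref in table.order and rank >= table.order.index(ref):
        return table.order[rank + 1]
    return table.order[rank]


def encode_stream(mismatches: str, refs: str, table: RankTable) -> bytes:
    """Rank-encode paired (mismatch, reference) symbol streams."""
    if len(mismatches) != len(refs):
        raise ValueError("mismatch/reference stream length mismatch")
    return bytes(rank_encode(m, r, table) for m, r in zip(mismatches, refs))


def decode_stream(ranks: bytes, refs: str, table: RankTable) -> str:
    if len(ranks) != len(refs):
        raise RankCorruptionError("rank/reference stream length mismatch")
    return "".join(rank_decode(k, r, table) for k, r in zip(ranks, refs))
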