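"""Pseudogenome construction: greedy shortest-common-superstring approximation.

Reads are chained by exact suffix-prefix overlaps (forward orientation only;
reverse-complement redundancy is removed downstream). The chaining is greedy
and sequential: reads are processed in input order, each chain is extended
rightward with the candidate offering the longest overlap not below
``min_overlap``, a consumed read is never re-linked (no cycles by
construction), and the single-worker result is the normative output. Chains
are merged by their overlaps and concatenated into the pseudogenome text;
each read's placement (offset, strand) is recorded so that every placed read
is exactly recoverable from the text.

Reads that chain with nothing can either be returned as leftovers (the
high-quality build — they are demoted to the mapping/low-quality path) or
placed as singleton chains (the PGlq / PGN builds, where nothing may be
discarded).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

from .io_fastq import reverse_complement


@dataclass(frozen=True)
class Placement:
    read_index: int
    offset: int
    strand: str = "fwd"  # {"fwd", "rc"}


@dataclass
class Pseudogenome:
    text: str
    placements: list[Placement]


@dataclass(frozen=True)
class OverlapParams:
    min_overlap: int | None = None  # None -> floor(min read length / 2)
    overlap_step: int = 1

    def resolve_min_overlap(self, seqs: Sequence[str]) -> int:
        if self.min_overlap is not None:
            return self.min_overlap
        if not seqs:
            return 1
        return max(1, min(len(s) for s in seqs) // 2)


def dedupe_reads(seqs: Sequence[str]) -> tuple[list[str], dict[str, list[int]]]:
    """Collapse exact duplicates, preserving first-occurrence order.

    Returns the unique sequences and a table mapping each unique sequence to
    the ordered list of original indices carrying it.
    """
    mult: dict[str, list[int]] = {}
    uniques: list[str] = []
    for i, s in enumerate(seqs):
        slot = mult.get(s)
        if slot is None:
            mult[s] = [i]
            uniques.append(s)
        else:
            slot.append(i)
    return uniques, mult


def _build_prefix_table(seqs: Sequence[str], min_ov: int):
    table: dict[str, list[int]] = defaultdict(list)
    for i, s in enumerate(seqs):
        if len(s) >= min_ov:
            table[s[:min_ov]].append(i)
    return table


def _best_successor(cur: str, table, seqs, consumed, min_ov: int, max_len: int):
    """Longest exact suffix-prefix overlap >= min_ov; ties -> lowest index."""
    len_cur = len(cur)
    hi = min(len_cur, max_len)
    for ov in range(hi, min_ov - 1, -1):
        key = cur[len_cur - ov:len_cur - ov + min_ov]
        tail = cur[len_cur - ov:]
        for j in table.get(key, ()):
            if consumed[j]:
                continue
            s = seqs[j]
            if len(s) >= ov and s.startswith(tail):
                return j, ov
    return None, 0


def find_best_successor(read_a: str, candidate_set: Sequence[str],
                        params: OverlapParams | None = None):
    """Candidate whose prefix has the longest overlap with ``read_a``'s suffix.

    Self-overlap is excluded by identity of position only when the candidate
    set contains ``read_a`` itself (callers pass deduplicated sets). Returns
    ``(index_into_candidate_set, overlap_len)`` or ``(None, 0)``.
    """
    params = params or OverlapParams()
    seqs = list(candidate_set)
    if not seqs:
        return None, 0
    min_ov = params.resolve_min_overlap(seqs)
    table = _build_prefix_table(seqs, min_ov)
    consumed = [s == read_a for s in seqs]  # forbid chaining a read to itself
    max_len = max(len(s) for s in seqs)
    return _best_successor(read_a, table, seqs, consumed, min_ov, max_len)


def build_pseudogenome(seqs: Sequence[str], params: OverlapParams | None = None,
                       keep_singletons: bool = False
                       ) -> tuple[Pseudogenome, list[int]]:
    """Greedy overlap chaining over (deduplicated) sequences.

    Returns the pseudogenome and the leftover indices (reads forming no
    chain); with ``keep_singletons`` leftovers are instead placed as
    singleton chains and the leftover list is empty.
    """
    params = params or OverlapParams()
    n = len(seqs)
    if n == 0:
        return Pseudogenome("", []), []
    min_ov = params.resolve_min_overlap(seqs)
    table = _build_prefix_table(seqs, min_ov)
    max_len = max(len(s) for s in seqs)
    consumed = [False] * n
    chains: list[list[tuple[int, int]]] = []  # [(read, overlap_with_prev)]
    for i in range(n):
        if consumed[i]:
            continue
        consumed[i] = True
        chain = [(i, 0)]
        cur = seqs[i]
        while True:
            j, ov = _best_successor(cur, table, seqs, consumed, min_ov, max_len)
            if j is None:
                break
            consumed[j] = True
            chain.append((j, ov))
            cur = seqs[j]
        chains.append(chain)

    parts: list[str] = []
    placements: list[Placement] = []
    leftovers: list[int] = []
    pos = 0
    for chain in chains:
        if len(chain) == 1 and not keep_singletons:
            leftovers.append(chain[0][0])
            continue
        for idx, ov in chain:
            s = seqs[idx]
            offset = pos - ov
            placements.append(Placement(idx, offset, "fwd"))
            parts.append(s[ov:])
            pos = offset + len(s)
    return Pseudogenome("".join(parts), placements), leftovers


def build_lq_and_n_pseudogenomes(lq_seqs: Sequence[str], n_seqs: Sequence[str],
                                 params: OverlapParams | None = None
                                 ) -> tuple[Pseudogenome, Pseudogenome]:
    """PGlq and PGN: same algorithm, singleton chains kept (no data loss)."""
    pg_lq, _ = build_pseudogenome(lq_seqs, params, keep_singletons=True)
    pg_n, _ = build_pseudogenome(n_seqs, params, keep_singletons=True)
    return pg_lq, pg_n


def extract_read(pg: Pseudogenome, placement: Placement, length: int) -> str:
    """Recover a placed read from the pseudogenome text."""
    window = pg.text[placement.offset:placement.offset + length]
    return reverse_complement(window) if placement.strand == "rc" else window


def verify_pseudogenome(pg: Pseudogenome, seqs: Sequence[str]) -> bool:
    """Check the reconstruction invariant for every placement."""
    return all(
        extract_read(pg, pl, len(seqs[pl.read_index])) == seqs[pl.read_index]
        for pl in pg.placements
    )
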