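"""Mismatch-tolerant mapping of residual reads onto the HQ pseudogenome.

Reads that did not enter PGhq (quality-rejected and overlap-leftover reads)
are aligned to it allowing up to floor(read_len / M) Hamming mismatches
(M = 3 by default). Candidate offsets come from a sparse-sampled k-mer index:
only pseudogenome positions divisible by ``step`` are stored, and the read's
k-mers at offsets 0 .. step-1 are probed in turn, which guarantees that any
alignment whose first k + step - 1 read symbols match exactly is found.
Both orientations are tried, forward first; within a probe round the
candidate with the fewest mismatches wins (ties: lowest offset), and the
first probe round producing an acceptable candidate ends the search.

Successfully mapped reads are encoded into several byte streams: offsets
(delta-coded in offset-sorted order), per-read mismatch counts, in-read
mismatch positions (delta-coded), raw mismatch symbols (rank-coded later),
packed strand flags, plus bookkeeping for order restoration.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

from ._util import ByteReader, encode_uvarint, pack_bits, unpack_bits
from .io_fastq import reverse_complement


@dataclass(frozen=True)
class MapperParams:
    M: int = 3           # mismatch divisor: allow floor(read_len / M)
    k: int = 36          # seed length
    step: int | None = None  # sampling stride; None -> k // 2

    def resolve_step(self) -> int:
        step = self.k // 2 if self.step is None else self.step
        if not 1 <= step <= self.k:
            raise ValueError(f"step {step} outside [1, k]")
        return step


@dataclass
class SparseIndex:
    k: int
    step: int
    table: dict[str, list[int]]


@dataclass(frozen=True)
class MappingResult:
    read_index: int
    mapped: bool
    read_length: int
    offset: int = 0
    strand: str = "fwd"
    mismatch_positions: tuple[int, ...] = ()
    mismatch_symbols: str = ""


def max_mismatches(read_length: int, M: int = 3) -> int:
    """floor(read_length / M): the per-read Hamming budget."""
    if read_length < 1 or M < 1:
        raise ValueError("need read_length >= 1 and M >= 1")
    return read_length // M


def build_sparse_index(text: str, params: MapperParams | None = None) -> SparseIndex:
    """Index the k-mer at every position divisible by ``step``; skip N/%."""
    params = params or MapperParams()
    k, step = params.k, params.resolve_step()
    table: dict[str, list[int]] = defaultdict(list)
    for p in range(0, len(text) - k + 1, step):
        km = text[p:p + k]
        if "N" in km or "%" in km:
            continue
        table[km].append(p)
    return SparseIndex(k, step, dict(table))


def _hamming_limited(a: str, b: str, limit: int) -> int | None:
    """Hamming distance, or None once it exceeds ``limit``."""
    if a == b:
        return 0
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return None
    return mm


def map_read(seq: str, index: SparseIndex, text: str,
             params: MapperParams | None = None,
             read_index: int = 0) -> MappingResult:
    """Seed-and-verify Hamming alignment of one read onto the pseudogenome."""
    params = params or MapperParams()
    L = len(seq)
    k, step = index.k, index.step
    unmapped = MappingResult(read_index, False, L)
    if L < k:
        return unmapped
    budget = max_mismatches(L, params.M)
    n = len(text)
    for strand in ("fwd", "rc"):
        target = seq if strand == "fwd" else reverse_complement(seq)
        for probe in range(step):
            if probe + k > L:
                break
            positions = index.table.get(target[probe:probe + k])
            if not positions:
                continue
            best_mm = budget + 1
            best_off = -1
            seen: set[int] = set()
            for p in positions:
                off = p - probe
                if off < 0 or off + L > n or off in seen:
                    continue
                seen.add(off)
                mm = _hamming_limited(target, text[off:off + L], best_mm - 1)
                if mm is not None and (mm < best_mm
                                       or (mm == best_mm and off < best_off)):
                    best_mm = mm
                    best_off = off
            if best_off >= 0:
                return _make_result(seq, target, text, best_off, strand,
                                    read_index)
    return unmapped


def _make_result(seq: str, target: str, text: str, offset: int, strand: str,
                 read_index: int) -> MappingResult:
    L = len(seq)
    window = text[offset:offset + L]
    tpos = [i for i in range(L) if target[i] != window[i]]
    if strand == "fwd":
        positions = tuple(tpos)
    else:
        positions = tuple(sorted(L - 1 - t for t in tpos))
    symbols = "".join(seq[p] for p in positions)
    return MappingResult(read_index, True, L, offset, strand, positions, symbols)


def reconstruct_read(result: MappingResult, text: str) -> str:
    """Rebuild a mapped read from the pseudogenome and its mismatch record."""
    L = result.read_length
    window = list(text[result.offset:result.offset + L])
    if result.strand == "fwd":
        for p, s in zip(result.mismatch_positions, result.mismatch_symbols):
            window[p] = s
        return "".join(window)
    for p, s in zip(result.mismatch_positions, result.mismatch_symbols):
        window[L - 1 - p] = reverse_complement(s)
    return reverse_complement("".join(window))


def reference_symbols(result: MappingResult, text: str) -> str:
    """Pseudogenome symbols (strand-adjusted) at the mismatch positions.

    These are the exclusion symbols for rank coding; by construction they
    always differ from the stored mismatch symbols.
    """
    L = result.read_length
    window = text[result.offset:result.offset + L]
    if result.strand == "fwd":
        return "".join(window[p] for p in result.mismatch_positions)
    return "".join(reverse_complement(window[L - 1 - p])
                   for p in result.mismatch_positions)


# ---------------------------------------------------------------------------
# Stream encoding
# ---------------------------------------------------------------------------

@dataclass
class MappingStreams:
    """Named byte streams for a list of mapping results."""

    offsets: bytes = b""     # deltas of offsets, sorted order, uvarint
    flags: bytes = b""       # strand bits, packed (1 = rc)
    counts: bytes = b""      # per-read mismatch counts, uvarint
    positions: bytes = b""   # within-read mismatch position deltas, uvarint
    symbols: bytes = b""     # raw mismatch symbols (rank-coded downstream)
    lengths: bytes = b""     # read lengths in sorted order, uvarint
    unmapped: bytes = b""    # unmapped read-index deltas, uvarint
    perm: bytes = b""        # mapped read_index per sorted slot, uvarint
    n_mapped: int = 0
    n_unmapped: int = 0

    def as_dict(self) -> dict[str, bytes]:
        return {
            "mm_offsets": self.offsets, "mm_flags": self.flags,
            "mm_counts": self.counts, "mm_pos": self.positions,
            "mm_syms": self.symbols, "mm_lengths": self.lengths,
            "mm_unmapped": self.unmapped, "mm_perm": self.perm,
        }


def emit_mapping_streams(results: Sequence[MappingResult]) -> MappingStreams:
    """Encode mapping results into delta/varint byte streams (bijective)."""
    mapped = sorted((r for r in results if r.mapped),
                    key=lambda r: (r.offset, r.read_index))
    unmapped = [r for r in results if not r.mapped]
    offsets = bytearray()
    counts = bytearray()
    positions = bytearray()
    lengths = bytearray()
    perm = bytearray()
    syms: list[str] = []
    bits: list[int] = []
    prev_off = 0
    for r in mapped:
        offsets += encode_uvarint(r.offset - prev_off)
        prev_off = r.offset
        bits.append(1 if r.strand == "rc" else 0)
        counts += encode_uvarint(len(r.mismatch_positions))
        prev = 0
        for p in r.mismatch_positions:
            positions += encode_uvarint(p - prev)
            prev = p
        syms.append(r.mismatch_symbols)
        lengths += encode_uvarint(r.read_length)
        perm += encode_uvarint(r.read_index)
    un = bytearray()
    prev = 0
    for r in sorted(unmapped, key=lambda r: r.read_index):
        un += encode_uvarint(r.read_index - prev)
        prev = r.read_index
        un += encode_uvarint(r.read_length)
    return MappingStreams(
        bytes(offsets), pack_bits(bits), bytes(counts), bytes(positions),
        "".join(syms).encode("ascii"), bytes(lengths), bytes(un), bytes(perm),
        len(mapped), len(unmapped),
    )


def decode_mapping_streams(streams: MappingStreams) -> list[MappingResult]:
    """Exact inverse of :func:`emit_mapping_streams` (original index order)."""
    n = streams.n_mapped
    offs = ByteReader(streams.offsets)
    cnts = ByteReader(streams.counts)
    poss = ByteReader(streams.positions)
    lens = ByteReader(streams.lengths)
    perm = ByteReader(streams.perm)
    bits = unpack_bits(streams.flags, n)
    syms = streams.symbols.decode("ascii")
    results: list[MappingResult] = []
    off = 0
    spos = 0
    for i in range(n):
        off += offs.read_uvarint()
        cnt = cnts.read_uvarint()
        mpos: list[int] = []
        p = 0
        for _ in range(cnt):
            p += poss.read_uvarint()
            mpos.append(p)
        results.append(MappingResult(
            perm.read_uvarint(), True, lens.read_uvarint(), off,
            "rc" if bits[i] else "fwd", tuple(mpos), syms[spos:spos + cnt],
        ))
        spos += cnt
    un = ByteReader(streams.unmapped)
    idx = 0
    for _ in range(streams.n_unmapped):
        idx += un.read_uvarint()
        results.append(MappingResult(idx, False, un.read_uvarint()))
    results.sort(key=lambda r: r.read_index)
    return results
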