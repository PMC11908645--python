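"""End-to-end DNA-stream compression and decompression.

Compression stages:

1. read-set division — N-containing reads, quality-rejected reads, and
   high-quality candidates;
2. PGhq — greedy shortest-common-superstring pseudogenome over deduplicated
   HQ reads; reads producing no long-enough overlap are demoted;
3. mismatch-tolerant mapping of the demoted + quality-rejected reads onto
   PGhq (up to floor(L/M) Hamming mismatches);
4. PGlq / PGN pseudogenomes over what remains;
5. reverse-complement repeat removal inside PGhq;
6. variable-length byte packing of all pseudogenome texts;
7. per-stream backend compression and archive assembly.

Modes: ``SE`` (order non-preserving single-end: the archive stores the read
multiset), ``SE_ORD`` (input order restored exactly), ``PE_ORD`` (two paired
files interleaved at even/odd original indices and restored exactly; the
index parity recovers the pair slot). Quality strings and headers are not
stored: decompressed FASTQ carries synthetic headers and a constant quality
character.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import backend_archive as ba
from . import mismatch_coder as mc
from . import rc_matcher as rc
from . import vlp_codec as vlp
from ._util import ByteReader, encode_deltas, encode_uvarint, pack_bits, unpack_bits
from .io_fastq import ReadRecord, reverse_complement
from .pg_builder import OverlapParams, build_pseudogenome, dedupe_reads
from .read_division import DivisionParams, divide_reads
from .read_mapper import (MapperParams, MappingResult, build_sparse_index,
                          map_read, reference_symbols)

MODES = ("SE", "SE_ORD", "PE_ORD")

#: quality character written on decompression (quality is not stored)
DECOMPRESS_QUAL = "I"


@dataclass(frozen=True)
class PipelineParams:
    division: DivisionParams = field(default_factory=DivisionParams)
    overlap: OverlapParams = field(default_factory=OverlapParams)
    mapper: MapperParams = field(default_factory=MapperParams)
    rc: rc.RcParams = field(default_factory=rc.RcParams)


@dataclass
class _Entity:
    """A unique sequence together with the original reads carrying it."""

    seq: str
    orig: list[int]


def _entities(records, indices) -> list[_Entity]:
    seqs = [records[i].seq for i in indices]
    uniques, mult = dedupe_reads(seqs)
    return [_Entity(u, [indices[j] for j in mult[u]]) for u in uniques]


def compress_records(records: list[ReadRecord], mode: str = "SE",
                     params: PipelineParams | None = None) -> ba.Archive:
    """Run the full pipeline over in-memory reads and build an archive."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    params = params or PipelineParams()
    lengths = {len(r.seq) for r in records}
    fixed_length = lengths.pop() if len(lengths) == 1 else None
    variable = fixed_length is None

    part = divide_reads(records, params.division)
    hq_entities = _entities(records, part.hq_candidates)
    n_entities = _entities(records, part.n_reads)

    pg_hq, hq_leftovers = build_pseudogenome(
        [e.seq for e in hq_entities], params.overlap)
    placed_hq = [hq_entities[pl.read_index] for pl in pg_hq.placements]

    # pool: quality-rejected reads + HQ overlap leftovers, deduplicated
    pool: dict[str, list[int]] = {}
    for i in part.lq_rejected:
        pool.setdefault(records[i].seq, []).append(i)
    for j in hq_leftovers:
        ent = hq_entities[j]
        pool.setdefault(ent.seq, []).extend(ent.orig)
    lq_entities = [_Entity(s, sorted(o)) for s, o in pool.items()]

    index = build_sparse_index(pg_hq.text, params.mapper)
    mapped: list[tuple[MappingResult, _Entity]] = []
    unmapped_entities: list[_Entity] = []
    for ent in lq_entities:
        res = map_read(ent.seq, index, pg_hq.text, params.mapper)
        if res.mapped:
            mapped.append((res, ent))
        else:
            unmapped_entities.append(ent)
    mapped.sort(key=lambda t: (t[0].offset, t[1].orig[0]))

    pg_lq, _ = build_pseudogenome([e.seq for e in unmapped_entities],
                                  params.overlap, keep_singletons=True)
    placed_lq = [unmapped_entities[pl.read_index] for pl in pg_lq.placements]
    pg_n, _ = build_pseudogenome([e.seq for e in n_entities],
                                 params.overlap, keep_singletons=True)
    placed_n = [n_entities[pl.read_index] for pl in pg_n.placements]

    # RC redundancy removal + packing
    matches = rc.find_rc_matches(pg_hq.text, params.rc)
    residual, rc_srcs, rc_lens = rc.apply_rc_matches(pg_hq.text, matches)
    d = vlp.build_packing_dictionary()

    all_syms = "".join(res.mismatch_symbols for res, _ in mapped)
    all_refs = "".join(reference_symbols(res, pg_hq.text) for res, _ in mapped)
    table = mc.build_rank_table(all_syms)

    streams: dict[str, bytes] = {
        "pg_hq_packed": vlp.pack(residual, d),
        "pg_lq_packed": vlp.pack(pg_lq.text, d),
        "pg_n_packed": vlp.pack(pg_n.text, d),
        "rc_srcs": b"".join(encode_uvarint(s) for s in rc_srcs),
        "rc_lens": b"".join(encode_uvarint(l) for l in rc_lens),
        "mm_ranks": mc.encode_stream(all_syms, all_refs, table),
    }

    def _placement_streams(prefix: str, pg, entities: list[_Entity]) -> None:
        streams[f"{prefix}_offsets"] = encode_deltas(
            [pl.offset for pl in pg.placements])
        streams[f"{prefix}_strands"] = pack_bits(
            [1 if pl.strand == "rc" else 0 for pl in pg.placements])
        streams[f"{prefix}_mults"] = b"".join(
            encode_uvarint(len(e.orig) - 1) for e in entities)
        if variable:
            streams[f"{prefix}_lengths"] = b"".join(
                encode_uvarint(len(e.seq)) for e in entities)

    _placement_streams("hq", pg_hq, placed_hq)
    _placement_streams("lq", pg_lq, placed_lq)
    _placement_streams("n", pg_n, placed_n)

    streams["mm_offsets"] = encode_deltas([res.offset for res, _ in mapped])
    streams["mm_flags"] = pack_bits(
        [1 if res.strand == "rc" else 0 for res, _ in mapped])
    streams["mm_counts"] = b"".join(
        encode_uvarint(len(res.mismatch_positions)) for res, _ in mapped)
    mm_pos = bytearray()
    for res, _ in mapped:
        prev = 0
        for p in res.mismatch_positions:
            mm_pos += encode_uvarint(p - prev)
            prev = p
    streams["mm_pos"] = bytes(mm_pos)
    streams["mm_mults"] = b"".join(
        encode_uvarint(len(e.orig) - 1) for _, e in mapped)
    if variable:
        streams["mm_lengths"] = b"".join(
            encode_uvarint(res.read_length) for res, _ in mapped)

    if mode in ("SE_ORD", "PE_ORD"):
        orig = bytearray()
        for group in (placed_hq, [e for _, e in mapped], placed_lq, placed_n):
            for ent in group:
                for i in ent.orig:
                    orig += encode_uvarint(i)
        streams["orig_indices"] = bytes(orig)

    header = {
        "mode": mode,
        "read_count": len(records),
        "fixed_length": fixed_length,
        "n_hq": len(pg_hq.placements),
        "n_mapped": len(mapped),
        "n_lq": len(pg_lq.placements),
        "n_n": len(pg_n.placements),
        "n_rc": len(rc_srcs),
        "rank_order": table.order,
        "params": {
            "check_fraction": params.division.check_fraction,
            "error_threshold": params.division.error_threshold,
            "M": params.mapper.M,
            "k": params.mapper.k,
            "min_rc_match": params.rc.min_rc_match,
        },
    }
    return ba.Archive(header, vlp.serialize_dictionary(d),
                      ba.compress_streams(streams))


def decompress_records(archive: ba.Archive) -> tuple[list[str], str]:
    """Recover the sequence list (in original index order) and the mode."""
    header = archive.header
    mode = header["mode"]
    fixed_length = header["fixed_length"]
    streams = ba.decompress_streams(archive)
    d = vlp.deserialize_dictionary(archive.vlp_blob)
    table = mc.RankTable(header["rank_order"])

    residual = vlp.unpack(streams["pg_hq_packed"], d)
    srcs = ByteReader(streams["rc_srcs"]).read_uvarints(header["n_rc"])
    lens = ByteReader(streams["rc_lens"]).read_uvarints(header["n_rc"])
    text_hq = rc.undo_rc_matches(residual, srcs, lens)
    text_lq = vlp.unpack(streams["pg_lq_packed"], d)
    text_n = vlp.unpack(streams["pg_n_packed"], d)

    emitted: list[tuple[str, int]] = []  # (sequence, multiplicity)

    def _read_placements(prefix: str, count: int, text: str) -> None:
        offsets = ByteReader(streams[f"{prefix}_offsets"]).read_deltas(count)
        strands = unpack_bits(streams[f"{prefix}_strands"], count)
        mults = ByteReader(streams[f"{prefix}_mults"]).read_uvarints(count)
        if fixed_length is None:
            lns = ByteReader(streams[f"{prefix}_lengths"]).read_uvarints(count)
        else:
            lns = [fixed_length] * count
        for off, sbit, m, L in zip(offsets, strands, mults, lns):
            seq = text[off:off + L]
            if sbit:
                seq = reverse_complement(seq)
            emitted.append((seq, m + 1))

    _read_placements("hq", header["n_hq"], text_hq)

    nm = header["n_mapped"]
    mm_offsets = ByteReader(streams["mm_offsets"]).read_deltas(nm)
    mm_flags = unpack_bits(streams["mm_flags"], nm)
    mm_counts = ByteReader(streams["mm_counts"]).read_uvarints(nm)
    mm_mults = ByteReader(streams["mm_mults"]).read_uvarints(nm)
    if fixed_length is None:
        mm_lengths = ByteReader(streams["mm_lengths"]).read_uvarints(nm)
    else:
        mm_lengths = [fixed_length] * nm
    pos_reader = ByteReader(streams["mm_pos"])
    ranks = streams["mm_ranks"]
    rpos = 0
    mapped_emitted: list[tuple[str, int]] = []
    for i in range(nm):
        L = mm_lengths[i]
        off = mm_offsets[i]
        strand = "rc" if mm_flags[i] else "fwd"
        positions = pos_reader.read_deltas(mm_counts[i])
        window = list(text_hq[off:off + L])
        symbols: list[str] = []
        for p in positions:
            if strand == "fwd":
                ref = window[p]
            else:
                ref = reverse_complement(window[L - 1 - p])
            symbols.append(mc.rank_decode(ranks[rpos], ref, table))
            rpos += 1
        for p, s in zip(positions, symbols):
            if strand == "fwd":
                window[p] = s
            else:
                window[L - 1 - p] = reverse_complement(s)
        seq = "".join(window)
        if strand == "rc":
            seq = reverse_complement(seq)
        mapped_emitted.append((seq, mm_mults[i] + 1))
    emitted.extend(mapped_emitted)

    _read_placements("lq", header["n_lq"], text_lq)
    _read_placements("n", header["n_n"], text_n)

    read_count = header["read_count"]
    total = sum(m for _, m in emitted)
    if total != read_count:
        raise ba.ArchiveCorruptionError(
            f"archive reconstructs {total} reads, header says {read_count}")

    if mode == "SE":
        out: list[str] = []
        for seq, m in emitted:
            out.extend([seq] * m)
        return out, mode
    orig = ByteReader(streams["orig_indices"])
    out = [""] * read_count
    seen = [False] * read_count
    for seq, m in emitted:
        for _ in range(m):
            i = orig.read_uvarint()
            if i >= read_count or seen[i]:
                raise ba.ArchiveCorruptionError(
                    f"invalid original index {i} in order stream")
            seen[i] = True
            out[i] = seq
    return out, mode


# ---------------------------------------------------------------------------
# File-level entry points
# ---------------------------------------------------------------------------

def compress_fastq(in_path, out_path, in2_path=None, preserve_order=False,
                   params: PipelineParams | None = None) -> dict:
    """Compress one or two FASTQ files into an archive; returns the header."""
    from .io_fastq import read_fastq

    if in2_path is not None:
        first = read_fastq(in_path, "first")
        second = read_fastq(in2_path, "second")
        if len(first) != len(second):
            raise ValueError(
                f"paired files differ in read count: {len(first)} vs "
                f"{len(second)}")
        records = []
        for a, b in zip(first, second):
            records.append(ReadRecord(a.seq, a.qual, 2 * a.orig_index, "first"))
            records.append(ReadRecord(b.seq, b.qual, 2 * b.orig_index + 1,
                                      "second"))
        mode = "PE_ORD"
    else:
        records = read_fastq(in_path)
        mode = "SE_ORD" if preserve_order else "SE"
    archive = compress_records(records, mode, params)
    ba.write_archive(out_path, archive)
    return archive.header


def decompress_fastq(in_path, out_path, out2_path=None,
                     fasta_seq_only=False) -> dict:
    """Decompress an archive back to FASTQ (or sequence-only FASTA)."""
    archive = ba.read_archive(in_path)
    seqs, mode = decompress_records(archive)
    if mode == "PE_ORD":
        if out2_path is None:
            raise ValueError("paired archive needs two output paths")
        pairs = [(seqs[i], seqs[i + 1]) for i in range(0, len(seqs), 2)]
        _write_seqs([p[0] for p in pairs], out_path, fasta_seq_only)
        _write_seqs([p[1] for p in pairs], out2_path, fasta_seq_only)
    else:
        _write_seqs(seqs, out_path, fasta_seq_only)
    return archive.header


def _write_seqs(seqs, path, fasta_seq_only):
    with open(path, "w") as out:
        for i, seq in enumerate(seqs):
            if fasta_seq_only:
                out.write(f">r{i}\n{seq}\n")
            else:
                out.write(f"@r{i}\n{seq}\n+\n{DECOMPRESS_QUAL * len(seq)}\n")
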