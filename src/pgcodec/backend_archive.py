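"""Backend stream compression and the archive container.

Each emitted stream is compressed with every codec in its candidate list and
the smallest output wins (ties go to the earlier candidate); the chosen codec
id is stored so decompression never re-tries. Codec identifiers are abstract
roles mapped to a concrete registry:

========  =====================================================
id        role
========  =====================================================
lzma      LZMA-class long-range LZ + range coding (pseudogenomes)
bz2       block-sorting statistical coder (context-model role)
zlib      fast LZ77 + Huffman (entropy-coder role)
stored    identity fallback — output is never larger than input
========  =====================================================

The packed pseudogenome streams go to LZMA only; the small bookkeeping
streams (ranks, counts, deltas, flags) get the multi-candidate treatment,
where the best choice genuinely varies with the data.

The container is a custom, versioned byte layout: magic, version, a JSON
header blob (mode, read counts, parameters, mismatch rank table), the
serialized packing dictionary, a stream directory with per-stream codec ids,
raw/compressed sizes and CRC32 checksums, then the payloads.
"""

from __future__ import annotations

import json
import lzma
import bz2
import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

from ._util import ByteReader, encode_uvarint

MAGIC = b"PGDC"
VERSION = 1


class ArchiveFormatError(ValueError):
    """Bad magic or unsupported version."""


class ArchiveCorruptionError(ValueError):
    """Checksum failure or truncated container; names the offending stream."""


# --- codec registry --------------------------------------------------------

_LZMA_FILTERS = [{"id": lzma.FILTER_LZMA2, "preset": 6}]


def _lzma_compress(data: bytes) -> bytes:
    return lzma.compress(data, format=lzma.FORMAT_RAW, filters=_LZMA_FILTERS)


def _lzma_decompress(data: bytes) -> bytes:
    return lzma.decompress(data, format=lzma.FORMAT_RAW, filters=_LZMA_FILTERS)


CODECS: dict[str, tuple[Callable[[bytes], bytes], Callable[[bytes], bytes]]] = {
    "lzma": (_lzma_compress, _lzma_decompress),
    "bz2": (lambda d: bz2.compress(d, 9), bz2.decompress),
    "zlib": (lambda d: zlib.compress(d, 9), zlib.decompress),
    "stored": (lambda d: d, lambda d: d),
}

#: fixed per-stream candidate table
_PG_CANDIDATES = ["lzma"]
_WIDE_CANDIDATES = ["zlib", "bz2", "lzma"]
_DEFAULT_CANDIDATES = ["lzma", "zlib"]

_CANDIDATE_TABLE: dict[str, list[str]] = {
    "pg_hq_packed": _PG_CANDIDATES,
    "pg_lq_packed": _PG_CANDIDATES,
    "pg_n_packed": _PG_CANDIDATES,
    "mm_ranks": _WIDE_CANDIDATES,
    "mm_counts": _WIDE_CANDIDATES,
    "mm_pos": _WIDE_CANDIDATES,
    "mm_offsets": _WIDE_CANDIDATES,
    "mm_flags": _WIDE_CANDIDATES,
    "mm_lengths": _WIDE_CANDIDATES,
    "rc_srcs": _WIDE_CANDIDATES,
    "rc_lens": _WIDE_CANDIDATES,
    "hq_offsets": _WIDE_CANDIDATES,
    "hq_strands": _WIDE_CANDIDATES,
    "hq_mults": _WIDE_CANDIDATES,
    "hq_lengths": _WIDE_CANDIDATES,
    "mm_mults": _WIDE_CANDIDATES,
    "lq_offsets": _WIDE_CANDIDATES,
    "lq_strands": _WIDE_CANDIDATES,
    "lq_mults": _WIDE_CANDIDATES,
    "lq_lengths": _WIDE_CANDIDATES,
    "n_offsets": _WIDE_CANDIDATES,
    "n_strands": _WIDE_CANDIDATES,
    "n_mults": _WIDE_CANDIDATES,
    "n_lengths": _WIDE_CANDIDATES,
    "orig_indices": _WIDE_CANDIDATES,
}


def assign_candidates(name: str) -> list[str]:
    """Candidate codec list for a named stream (unknown -> default pair)."""
    return list(_CANDIDATE_TABLE.get(name, _DEFAULT_CANDIDATES))


@dataclass(frozen=True)
class StreamSpec:
    name: str
    data: bytes
    candidates: tuple[str, ...] = ()

    def resolved_candidates(self) -> list[str]:
        return list(self.candidates) if self.candidates else assign_candidates(self.name)


def compress_stream(spec: StreamSpec) -> tuple[str, bytes]:
    """Try every candidate codec, return the smallest output.

    ``stored`` always participates as the final implicit candidate, so the
    result is never larger than the input; a codec raising is skipped rather
    than failing the pipeline.
    """
    best_id, best = "stored", spec.data
    for codec_id in spec.resolved_candidates():
        if codec_id == "stored":
            continue
        try:
            out = CODECS[codec_id][0](spec.data)
        except Exception:
            continue
        if len(out) < len(best):
            best_id, best = codec_id, out
    return best_id, best


def decompress_stream(codec_id: str, data: bytes) -> bytes:
    if codec_id not in CODECS:
        raise ArchiveFormatError(f"unknown codec id {codec_id!r}")
    return CODECS[codec_id][1](data)


# --- container -------------------------------------------------------------

@dataclass
class CompressedStream:
    name: str
    codec_id: str
    raw_size: int
    payload: bytes


@dataclass
class Archive:
    header: dict
    vlp_blob: bytes
    streams: list[CompressedStream] = field(default_factory=list)


def _write_blob(out: bytearray, blob: bytes) -> None:
    out += encode_uvarint(len(blob))
    out += blob


def write_archive(path, archive: Archive) -> None:
    """Serialise the container (bit-exact, rereadable by read_archive)."""
    out = bytearray(MAGIC)
    out += encode_uvarint(VERSION)
    _write_blob(out, json.dumps(archive.header, sort_keys=True).encode("utf-8"))
    _write_blob(out, archive.vlp_blob)
    out += encode_uvarint(len(archive.streams))
    for s in archive.streams:
        _write_blob(out, s.name.encode("ascii"))
        _write_blob(out, s.codec_id.encode("ascii"))
        out += encode_uvarint(s.raw_size)
        out += encode_uvarint(len(s.payload))
        out += zlib.crc32(s.payload).to_bytes(4, "little")
    for s in archive.streams:
        out += s.payload
    with open(path, "wb") as fh:
        fh.write(out)


def read_archive(path) -> Archive:
    """Parse and verify a container; inverse of :func:`write_archive`."""
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:4] != MAGIC:
        raise ArchiveFormatError("bad archive magic")
    r = ByteReader(data)
    r.pos = 4
    try:
        version = r.read_uvarint()
        if version != VERSION:
            raise ArchiveFormatError(f"unsupported archive version {version}")
        header = json.loads(r.read_bytes(r.read_uvarint()).decode("utf-8"))
        vlp_blob = r.read_bytes(r.read_uvarint())
        n = r.read_uvarint()
        entries = []
        for _ in range(n):
            name = r.read_bytes(r.read_uvarint()).decode("ascii")
            codec_id = r.read_bytes(r.read_uvarint()).decode("ascii")
            raw_size = r.read_uvarint()
            comp_size = r.read_uvarint()
            crc = int.from_bytes(r.read_bytes(4), "little")
            entries.append((name, codec_id, raw_size, comp_size, crc))
        streams = []
        for name, codec_id, raw_size, comp_size, crc in entries:
            payload = r.read_bytes(comp_size)
            if zlib.crc32(payload) != crc:
                raise ArchiveCorruptionError(
                    f"checksum mismatch in stream {name!r}")
            streams.append(CompressedStream(name, codec_id, raw_size, payload))
    except ArchiveCorruptionError:
        raise
    except ArchiveFormatError:
        raise
    except ValueError as exc:
        raise ArchiveCorruptionError(f"truncated or malformed archive: {exc}")
    return Archive(header, vlp_blob, streams)


def compress_streams(raw: dict[str, bytes]) -> list[CompressedStream]:
    """Compress a named stream bundle with per-stream candidate selection."""
    out = []
    for name, data in raw.items():
        codec_id, payload = compress_stream(StreamSpec(name, data))
        out.append(CompressedStream(name, codec_id, len(data), payload))
    return out


def decompress_streams(archive: Archive) -> dict[str, bytes]:
    out: dict[str, bytes] = {}
    for s in archive.streams:
        data = decompress_stream(s.codec_id, s.payload)
        if len(data) != s.raw_size:
            raise ArchiveCorruptionError(
                f"stream {s.name!r} decompressed to {len(data)} bytes, "
                f"expected {s.raw_size}")
        out[s.name] = data
    return out
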