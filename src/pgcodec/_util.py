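"""Small binary helpers: LEB128 varints and bit packing."""

from __future__ import annotations

from typing import Iterable, Sequence


class StreamDecodeError(ValueError):
    pass


def encode_uvarint(value: int) -> bytes:
    """Unsigned LEB128."""
    if value < 0:
        raise ValueError("uvarint cannot encode negative values")
    out = bytearray()
    while True:
        byte = value & 0x7F
        value >>= 7
        if value:
            out.append(byte | 0x80)
        else:
            out.append(byte)
            return bytes(out)


def encode_uvarints(values: Iterable[int]) -> bytes:
    out = bytearray()
    for v in values:
        out += encode_uvarint(v)
    return bytes(out)


def encode_deltas(values: Sequence[int]) -> bytes:
    """Delta-code a non-decreasing sequence as uvarints."""
    out = bytearray()
    prev = 0
    for v in values:
        if v < prev:
            raise ValueError("delta coding requires a non-decreasing sequence")
        out += encode_uvarint(v - prev)
        prev = v
    return bytes(out)


class ByteReader:
    """Sequential reader over a bytes object."""

    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def read_uvarint(self) -> int:
        value = 0
        shift = 0
        while True:
            if self.pos >= len(self.data):
                raise StreamDecodeError("truncated uvarint")
            byte = self.data[self.pos]
            self.pos += 1
            value |= (byte & 0x7F) << shift
            if not byte & 0x80:
                return value
            shift += 7

    def read_uvarints(self, count: int) -> list[int]:
        return [self.read_uvarint() for _ in range(count)]

    def read_deltas(self, count: int) -> list[int]:
        out: list[int] = []
        acc = 0
        for _ in range(count):
            acc += self.read_uvarint()
            out.append(acc)
        return out

    def read_bytes(self, count: int) -> bytes:
        if self.pos + count > len(self.data):
            raise StreamDecodeError("truncated byte field")
        chunk = self.data[self.pos:self.pos + count]
        self.pos += count
        return chunk

    @property
    def exhausted(self) -> bool:
        return self.pos >= len(self.data)


def pack_bits(bits: Sequence[int]) -> bytes:
    """Pack 0/1 flags LSB-first into bytes."""
    out = bytearray((len(bits) + 7) // 8)
    for i, b in enumerate(bits):
        if b:
            out[i >> 3] |= 1 << (i & 7)
    return bytes(out)


def unpack_bits(data: bytes, count: int) -> list[int]:
    if len(data) < (count + 7) // 8:
        raise StreamDecodeError("truncated bit stream")
    return [(data[i >> 3] >> (i & 7)) & 1 for i in range(count)]
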