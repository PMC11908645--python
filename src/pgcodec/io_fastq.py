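"""FASTQ input/output and synthetic read-set generation.

The compressor only retains the DNA stream of a FASTQ file; quality strings
are read (they drive read-set division) but never stored in an archive.
Sequences are normalised to the 5-symbol alphabet {A, C, G, T, N}: lowercase
bases are uppercased and anything else becomes N.
"""

from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

DNA_ALPHABET = "ACGTN"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Full 256-entry sanitation table: keep ACGTN, uppercase acgtn, map the rest
# (IUPAC ambiguity codes, '.', '-', ...) to N.
_SANITIZE = str.maketrans(
    {c: ("N" if chr(c).upper() not in "ACGT" else chr(c).upper()) for c in range(256)}
)


class FastqParseError(ValueError):
    """Raised on malformed FASTQ input; the message names the record ordinal."""


def reverse_complement(s: str) -> str:
    """Reverse-complement a string over {A,C,G,T,N} (N maps to N)."""
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: DNA symbols, Phred+33 quality, provenance."""

    seq: str
    qual: str
    orig_index: int
    pair_slot: str = "none"  # {"none", "first", "second"}

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.orig_index}: seq length {len(self.seq)} != "
                f"qual length {len(self.qual)}"
            )


def _open_text(path) -> io.TextIOBase:
    """Open plain or gzipped text, sniffing the gzip magic bytes."""
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=fh), encoding="ascii")
    return io.TextIOWrapper(fh, encoding="ascii")


def read_fastq(path, pair_slot: str = "none") -> list[ReadRecord]:
    """Parse a (possibly gzipped) 4-line-per-record FASTQ file.

    Sequences are sanitised to {A,C,G,T,N}. Malformed records raise
    :class:`FastqParseError` naming the 0-based record ordinal.
    """
    records: list[ReadRecord] = []
    with _open_text(path) as handle:
        it = FastqGeneralIterator(handle)
        i = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                break
            except ValueError as exc:
                raise FastqParseError(f"malformed FASTQ record {i}: {exc}") from exc
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"malformed FASTQ record {i}: seq/qual length mismatch"
                )
            for ch in qual:
                if not 33 <= ord(ch) <= 126:
                    raise FastqParseError(
                        f"malformed FASTQ record {i}: quality code {ord(ch)} "
                        "outside [33, 126]"
                    )
            records.append(
                ReadRecord(seq.translate(_SANITIZE), qual, i, pair_slot)
            )
            i += 1
    return records


def write_fastq(records: Iterable[ReadRecord], path) -> None:
    """Write records as plain 4-line FASTQ with synthetic ``@r<i>`` headers."""
    with open(path, "w") as out:
        for rec in records:
            out.write(f"@r{rec.orig_index}\n{rec.seq}\n+\n{rec.qual}\n")


def write_fasta(records: Iterable[ReadRecord], path) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(f">r{rec.orig_index}\n{rec.seq}\n")


# ---------------------------------------------------------------------------
# Synthetic read sets
# ---------------------------------------------------------------------------

#: quality characters used by the generator
_Q_HIGH = "I"      # code 73, Phred 40
_Q_SUB = "+"       # code 43, Phred 10 — dip at substituted bases
_Q_N = "#"         # code 35, Phred 2 — N calls
_REJECTING_CODES = (33, 34, 35)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a simulated high-coverage resequencing experiment."""

    ref_length: int = 10_000
    coverage: float = 10.0
    read_length: int = 100
    substitution_rate: float = 0.0
    n_rate: float = 0.0
    rc_fraction: float = 0.0
    low_quality_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("substitution_rate", "n_rate", "rc_fraction",
                     "low_quality_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (self.ref_length >= self.read_length >= 1):
            raise ValueError("need ref_length >= read_length >= 1")


@dataclass
class ReadLog:
    """Ground truth for one generated read (final read coordinates)."""

    start: int
    rc: bool
    sub_positions: tuple[int, ...]
    n_positions: tuple[int, ...]
    low_quality: bool


@dataclass
class SyntheticReadSet:
    reference: str
    reads: list[ReadRecord]
    log: list[ReadLog]

    def __iter__(self):  # allows ``ref, reads = generate_synthetic_reads(spec)``
        return iter((self.reference, self.reads))


def _check_position(read_length: int, check_fraction: float = 0.12) -> int:
    d = math.floor(check_fraction * read_length)
    return min(max(read_length - d, 0), read_length - 1)


def generate_synthetic_reads(spec: SyntheticSpec) -> SyntheticReadSet:
    """Simulate reads from a random reference.

    Reads are uniform windows of the reference with per-base substitution
    errors, N injection, optional reverse-complementation, and a two-level
    quality model: high everywhere, dipped at error positions, and — for a
    ``low_quality_fraction`` of reads — a rejecting character (ASCII 33-35)
    at the read-set-division check position. Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    ref = rng.integers(0, 4, spec.ref_length)
    reference = ref.view()  # int codes
    ref_str = bases[ref].tobytes().decode("ascii")

    n_reads = int(spec.coverage * spec.ref_length / spec.read_length)
    L = spec.read_length
    starts = rng.integers(0, spec.ref_length - L + 1, n_reads)
    check_pos = _check_position(L)

    reads: list[ReadRecord] = []
    log: list[ReadLog] = []
    errorful = (spec.substitution_rate > 0 or spec.n_rate > 0)
    for i in range(n_reads):
        start = int(starts[i])
        seq = ref_str[start:start + L]
        sub_pos: list[int] = []
        n_pos: list[int] = []
        if errorful:
            symbols = list(seq)
            u = rng.random(L)
            for p in np.flatnonzero(u < spec.substitution_rate):
                p = int(p)
                # substitute with one of the three *other* bases
                old = symbols[p]
                choices = [b for b in "ACGT" if b != old]
                symbols[p] = choices[int(rng.integers(0, 3))]
                sub_pos.append(p)
            un = rng.random(L)
            for p in np.flatnonzero(un < spec.n_rate):
                p = int(p)
                symbols[p] = "N"
                n_pos.append(p)
                if p in sub_pos:
                    sub_pos.remove(p)
            seq = "".join(symbols)
        qual = [_Q_HIGH] * L
        for p in sub_pos:
            qual[p] = _Q_SUB
        for p in n_pos:
            qual[p] = _Q_N
        is_rc = spec.rc_fraction > 0 and rng.random() < spec.rc_fraction
        if is_rc:
            seq = reverse_complement(seq)
            qual.reverse()
            sub_pos = sorted(L - 1 - p for p in sub_pos)
            n_pos = sorted(L - 1 - p for p in n_pos)
        is_lq = (spec.low_quality_fraction > 0
                 and rng.random() < spec.low_quality_fraction)
        if is_lq:
            qual[check_pos] = chr(_REJECTING_CODES[int(rng.integers(0, 3))])
        reads.append(ReadRecord(seq, "".join(qual), i))
        log.append(ReadLog(start, is_rc, tuple(sub_pos), tuple(n_pos), is_lq))
    return SyntheticReadSet(ref_str, reads, log)
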