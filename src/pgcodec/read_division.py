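"""Read-set division: N-containing, quality-rejected, and HQ-candidate reads.

A single quality character per read is inspected, at a fixed distance from
the read's end (0.12 of the read length by default). If its Phred error
probability exceeds 63% — i.e. Phred quality 2 and below, ASCII codes
33, 34, 35 at offset 33 — the whole read is rejected from the high-quality
candidates. Reads containing at least one N form their own subset and are
never quality-checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .io_fastq import ReadRecord


@dataclass(frozen=True)
class DivisionParams:
    check_fraction: float = 0.12
    error_threshold: float = 0.63
    phred_offset: int = 33

    def __post_init__(self):
        if not 0.0 < self.check_fraction < 1.0:
            raise ValueError("check_fraction must be in (0, 1)")
        if not 0.0 < self.error_threshold < 1.0:
            raise ValueError("error_threshold must be in (0, 1)")


@dataclass
class ReadPartition:
    hq_candidates: list[int]
    lq_rejected: list[int]
    n_reads: list[int]


def check_position(read_length: int, check_fraction: float = 0.12) -> int:
    """0-based index of the inspected quality character.

    ``read_length - floor(check_fraction * read_length)``, clamped into the
    read; "d symbols from the end" counts the last symbol as the 1st, so at
    L=100 and fraction 0.12 this is index 88, the 12th symbol from the end.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    d = math.floor(check_fraction * read_length)
    return min(max(read_length - d, 0), read_length - 1)


def phred_error(qchar: str, phred_offset: int = 33) -> float:
    """Error probability 10^(-Q/10) of a Phred+``offset`` quality character."""
    code = ord(qchar)
    if code < phred_offset:
        raise ValueError(f"quality code {code} below Phred offset {phred_offset}")
    return 10.0 ** (-(code - phred_offset) / 10.0)


def is_quality_rejected(read: ReadRecord, params: DivisionParams | None = None) -> bool:
    """True iff the check-position quality signals an unreliable read.

    With default parameters this holds exactly for ASCII codes {33, 34, 35}
    (Phred 0-2): the comparison is strictly-greater, so Phred 3 (~50.1%
    error) is kept while Phred 2 (~63.1%) is rejected.
    """
    params = params or DivisionParams()
    pos = check_position(len(read.seq), params.check_fraction)
    return phred_error(read.qual[pos], params.phred_offset) > params.error_threshold


def divide_reads(reads: Sequence[ReadRecord],
                 params: DivisionParams | None = None) -> ReadPartition:
    """Partition reads into N-containing / quality-rejected / HQ candidates.

    The N check comes first: a read with both an N and a rejecting quality
    character is classed as an N-read. The three lists are disjoint, cover
    the input, and preserve input order.
    """
    params = params or DivisionParams()
    part = ReadPartition([], [], [])
    for i, read in enumerate(reads):
        if "N" in read.seq:
            part.n_reads.append(i)
        elif len(read.seq) == 0 or is_quality_rejected(read, params):
            part.lq_rejected.append(i)
        else:
            part.hq_candidates.append(i)
    assert (len(part.hq_candidates) + len(part.lq_rejected)
            + len(part.n_reads)) == len(reads)
    return part
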