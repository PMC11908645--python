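"""Variable-length packing of pseudogenome text into bytes.

Up to 4 bases are packed per byte using a fixed dictionary of 242 phrases
(lengths 1-4) over {A, C, G, T, N, %}. Codes are assigned by ordering each
group of phrases by their *reversed* strings (TAA immediately precedes ATAA),
and each group of phrases ending in a new standard symbol (A, C, G, T) starts
at a multiple of 64. Because phrase lengths vary, two packings of texts
sharing a long substring quickly re-synchronise to identical byte runs after
a phrase-boundary phase shift, so LZ77-class matches largely survive the
transform; the reversal ordering additionally keeps codes of same-suffix
phrases numerically close, which helps the LZMA backend.

The canonical dictionary (frequency-independent, universal):

* per terminal symbol t in (A, C, G, T), a 64-slot group holding
  - all 21 phrases over {A,C,G,T} of length 1-3 ending in t,
  - the two length-2 phrases ``N``+t and ``%``+t,
  - the first 37 length-4 {A,C,G,T} phrases ending in t in
    reversal-lexicographic order,
  all sorted together by their reversals (60 used slots per group);
* the singleton phrases ``N`` and ``%`` at reserved codes 252 and 253.

Total: 4 x 60 + 2 = 242 phrases; 14 of the 256 byte values are unused.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

PACKED_ALPHABET = "ACGTN%"

#: symbol order used for reversal-lexicographic sorting
_SYM_ORDER = {c: i for i, c in enumerate(PACKED_ALPHABET)}

_N_CODE = 252
_PCT_CODE = 253
_L4_PER_GROUP = 37
_GROUP_SIZE = 64


class VlpCorruptionError(ValueError):
    """A packed byte maps to an unused dictionary slot."""


@dataclass(frozen=True)
class PackingDictionary:
    phrases: tuple[str, ...]              # all 242 phrases
    code_of: dict[str, int]
    phrase_of: dict[int, str]
    max_phrase_len: int = 4


def _revkey(phrase: str) -> tuple[int, ...]:
    return tuple(_SYM_ORDER[c] for c in reversed(phrase))


def build_packing_dictionary() -> PackingDictionary:
    """Build the canonical 242-phrase dictionary (deterministic)."""
    code_of: dict[str, int] = {}
    phrase_of: dict[int, str] = {}
    for gi, t in enumerate("ACGT"):
        group: list[str] = []
        for L in (1, 2, 3):
            group.extend("".join(pre) + t for pre in product("ACGT", repeat=L - 1))
        group.extend(("N" + t, "%" + t))
        l4 = sorted(("".join(pre) + t for pre in product("ACGT", repeat=3)),
                    key=_revkey)
        group.extend(l4[:_L4_PER_GROUP])
        group.sort(key=_revkey)
        base = gi * _GROUP_SIZE
        for j, p in enumerate(group):
            code_of[p] = base + j
            phrase_of[base + j] = p
    code_of["N"] = _N_CODE
    phrase_of[_N_CODE] = "N"
    code_of["%"] = _PCT_CODE
    phrase_of[_PCT_CODE] = "%"
    phrases = tuple(phrase_of[c] for c in sorted(phrase_of))
    return PackingDictionary(phrases, code_of, phrase_of)


def pack(text: str, d: PackingDictionary) -> bytes:
    """Greedy longest-prefix parse of ``text`` into dictionary codes.

    Every single symbol of the 6-letter alphabet is a phrase, so the parse
    always advances; it is unique given the dictionary.
    """
    code_of = d.code_of
    out = bytearray()
    i = 0
    n = len(text)
    while i < n:
        code = code_of.get(text[i:i + 4])
        if code is None:
            code = code_of.get(text[i:i + 3])
            if code is None:
                code = code_of.get(text[i:i + 2])
                if code is None:
                    code = code_of[text[i]]
                    i += 1
                else:
                    i += 2
            else:
                i += 3
        else:
            i += 4
        out.append(code)
    return bytes(out)


def unpack(packed: bytes, d: PackingDictionary) -> str:
    """Exact inverse of :func:`pack` (bytewise phrase concatenation)."""
    phrase_of = d.phrase_of
    try:
        return "".join([phrase_of[b] for b in packed])
    except KeyError as exc:
        raise VlpCorruptionError(
            f"packed stream contains unused code {exc.args[0]}"
        ) from exc


# ---------------------------------------------------------------------------
# Archive header serialisation ("VLPDICT" section)
# ---------------------------------------------------------------------------

_MAGIC = b"VLPDICT"


def serialize_dictionary(d: PackingDictionary) -> bytes:
    """count, then (code, length, phrase) in code order."""
    out = bytearray(_MAGIC)
    out.append(len(d.phrases) & 0xFF)
    out.append(len(d.phrases) >> 8)
    for code in sorted(d.phrase_of):
        p = d.phrase_of[code]
        out.append(code)
        out.append(len(p))
        out.extend(p.encode("ascii"))
    return bytes(out)


def deserialize_dictionary(blob: bytes) -> PackingDictionary:
    if blob[:len(_MAGIC)] != _MAGIC:
        raise VlpCorruptionError("bad VLPDICT section magic")
    pos = len(_MAGIC)
    count = blob[pos] | (blob[pos + 1] << 8)
    pos += 2
    code_of: dict[str, int] = {}
    phrase_of: dict[int, str] = {}
    for _ in range(count):
        code = blob[pos]
        plen = blob[pos + 1]
        phrase = blob[pos + 2:pos + 2 + plen].decode("ascii")
        pos += 2 + plen
        code_of[phrase] = code
        phrase_of[code] = phrase
    phrases = tuple(phrase_of[c] for c in sorted(phrase_of))
    return PackingDictionary(phrases, code_of, phrase_of)
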