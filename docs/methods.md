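# Methods

## Model and assumptions

The compressor treats a short-read DNA stream as a noisy, redundant sample
of an unknown underlying sequence. It never reconstructs that sequence;
instead it builds a *pseudogenome* — a greedy approximation of the shortest
common superstring (SCS) over the high-quality reads — and re-expresses
every read as a pointer into it. The approach assumes substitution-dominated
short reads (Hamming mismatches only; no indels), an in-memory working set,
and an alphabet of `{A,C,G,T,N}`. Exact SCS is NP-hard; the greedy
suffix–prefix chaining used here is the standard constant-factor
approximation and is treated as a heuristic whose only hard contract is
that every placed read is recoverable verbatim from `(text, offset,
strand)`.

All stages are sequential and deterministic: identical inputs and
parameters produce byte-identical archives. Concurrent variants are
permitted by the design only if they reproduce the single-worker output
(streams may be compressed in parallel since per-stream outputs are
independent); no threading is implemented here and the `-t` CLI option is
accepted purely for interface stability.

## Pipeline parameters

| parameter | default | units | role |
|---|---|---|---|
| `check_fraction` | 0.12 | fraction of read length | quality-check position, `L − ⌊0.12·L⌋`, i.e. 12 symbols from the end at L=100 |
| `error_threshold` | 0.63 | probability | reject a read whose check-position Phred error exceeds this; with Phred+33 this is exactly codes {33,34,35} (Phred ≤ 2) |
| `min_overlap` | `⌊min read length / 2⌋` | bases | minimum exact suffix–prefix overlap for pseudogenome chaining |
| `M` | 3 | divisor | mismatch budget `⌊L/M⌋` per mapped read (33 at L=100) |
| `k` | 36 | bases | seed k-mer length of the sparse mapping index |
| `step` | `k/2` = 18 | positions | index sampling stride; probing read offsets `0…step−1` guarantees detection when the first `k+step−1` read symbols match exactly |
| `min_rc_match` | 48 | bases | minimum reverse-complement repeat length excised from PGhq |
| `rc_k`, `rc_step` | 32, 16 | bases / positions | RC-search probe length and sampling stride; `rc_k + rc_step − 1 ≤ min_rc_match` preserves the detection guarantee |

The quality comparison is strictly-greater: Phred 3 (≈50.1% error) is kept,
Phred 2 (≈63.1%) rejected. The check-position distance uses `floor`, and
"d symbols from the end" counts the last symbol as the first. The N-check
precedes the quality check: a read with both goes to the N subset.
`min_overlap` is deliberately conservative (half a read); smaller values
merge more aggressively but admit spurious joins that inflate the mapped
and PGlq streams.

## Design choices in genuinely open territory

* **Greedy chaining order.** Reads are processed in input order; each chain
  grows rightward with the longest-overlap available successor (ties to the
  lowest read index); consumed reads are never re-linked, so cycles are
  impossible by construction. Chain-with-nothing reads are *leftovers*:
  demoted to the mapping path in the HQ build, but placed as singleton
  chains in the PGlq/PGN builds, where nothing may be discarded.
* **Forward-only overlaps.** The builder ignores reverse-complement
  overlaps; RC redundancy is handled once, downstream, by the RC-repeat
  pass over the finished PGhq text. This keeps the two concerns independent
  and the chaining index simple (a single prefix table keyed on the first
  `min_overlap` characters).
* **Mapping candidate policy.** Orientations are tried forward first; probe
  offsets `0…step−1` in turn; within a probe round the fewest-mismatch
  candidate wins (ties to the lowest offset) and the first acceptable round
  ends the search. Reads whose seed region itself is corrupted are missed
  and simply fall through to PGlq — the pipeline tolerates missed matches,
  it never depends on finding them.
* **RC-repeat encoding.** The later occurrence is excised and replaced by a
  single in-band `%` sentinel; `(source offset, length)` pairs travel in
  dedicated streams. Sentinels are expanded left-to-right at decompression
  against the already-rebuilt text; accepting only matches with
  `src_end ≤ dest_start` guarantees the source is always available, while
  still allowing a later match's source to sit inside an earlier match's
  expanded region.
* **Packing dictionary.** The 242 phrases are fixed and
  frequency-independent, so the dictionary is universal and archives carry
  no corpus statistics. Each terminal group (A/C/G/T, starting at codes
  0/64/128/192) holds all 21 length-≤3 pure-ACGT phrases ending in that
  symbol, the two length-2 phrases `N·t` and `%·t`, and the first 37
  length-4 pure-ACGT phrases in reversal-lexicographic order; singleton `N`
  and `%` live at reserved codes 252/253; 14 byte values stay unused.
  Every single symbol is a phrase, so the greedy longest-prefix parse can
  never fail. The dictionary is serialised into every archive (~1 kB), so
  decoding never depends on reconstruction.
* **Rank coding.** Mismatch symbols are ranked by global order-0 frequency
  (ties broken A<C<G<N<T; empty stream falls back to A,C,G,T,N) and shifted
  down by one when above the excluded reference symbol, so ranks fit in
  `[0,3]`. Context modelling is deliberately omitted — order-0 statistics
  capture nearly all of the gain here. The 5-symbol order travels in the
  archive header.
* **Backend registry.** Codec identifiers are roles: `lzma` (long-range
  LZ + range coder; the only candidate for packed pseudogenomes), `bz2`
  (block-sorting statistical coder), `zlib` (fast LZ/entropy role), and
  `stored` (identity, an implicit final candidate so no stream ever grows).
  Every candidate is run and the smallest output wins; ties go to the
  earlier candidate, and a failing codec is skipped rather than failing the
  pipeline.
* **Order restoration.** SE mode stores no permutation (the archive is a
  read multiset). The order-preserving modes store one original index per
  emitted read copy. Paired files are interleaved at even/odd original
  indices, so index parity recovers the pair slot and no separate slot
  stream is needed.
* **Variable read lengths** are supported as a superset of the fixed-length
  case: per-entity length streams are emitted only when lengths vary.

## Numerical and degenerate-input choices

Delta streams are unsigned LEB128 varints over non-decreasing sequences
(placement and mapping offsets are emitted in sorted order precisely so the
deltas are small and non-negative). Strand flags are LSB-first packed bits.
Per-stream CRC32 checksums make corruption errors precise to the stream.
Empty inputs, empty subsets, all-N read sets, reads shorter than the seed
length (unmappable by construction), and zero-length reads (routed to the
low-quality path; quality cannot be inspected) all round-trip; every such
case is exercised in the test suite.

## The synthetic generator

`generate_synthetic_reads` emulates high-coverage resequencing: uniform
read starts over a uniform-random reference, per-base substitutions
(`substitution_rate`), N injection (`n_rate`), strand flips
(`rc_fraction`), and a two-level quality model — high (code 73) everywhere,
dipped at substituted (code 43) and N (code 35) bases, with a
`low_quality_fraction` of reads given a rejecting code (33–35) at the
division check position. The generator keeps a ground-truth log (source
window, strand, error positions, low-quality flag) that tests assert
against. Defaults used across the suite: read length 100, coverage 5–40,
substitution rates 0–3%, N rates 0–1%, `rc_fraction` 0.5 — the regime of
short-read resequencing data.

What it does **not** emulate: non-uniform coverage, GC bias, indels,
adapter contamination, realistic per-cycle quality decay, or genuine
genomic repeat structure. Passing tests therefore demonstrate correctness
(losslessness, invariants) on substitution-noise resequencing-like data and
*sanity* of compression behaviour; they do not predict compression ratios
on real accessions, which depend on repeat content and error profiles the
generator does not model.

## Problem sizes

The test battery uses 50 seeded datasets from a few hundred up to 50,000
reads × 100 bp, and the compression-effectiveness check runs 300,000
error-free reads (30× coverage of a 1 Mbp reference), where the archive
measures ≈5% of the 2-bit baseline and packing shrinks the PGhq stream
≈3.6-fold. These sizes were chosen as the smallest at which coverage
redundancy, mapping and RC-removal all engage meaningfully.

## Match preservation under packing

The packing transform preserves LZ matches statistically, not exactly: two
parses of a shared substring entering at different phrase phases
re-synchronise when their boundary sets first intersect, a random-walk
absorption whose tail is heavier than its median. Calibrated once on 1,000
planted-substring trials (|s|=200 inside random 1,000-base contexts), the
frozen assertions are: median surviving common span ≥ |s|−16 symbols, and
span ≥ |s|−64 in ≥90% of trials (measured 96.3%). These constants are part
of the test contract, not tunables.

## Known limitations

* Compression ratio is not competitive with optimised C++ tools on large
  real datasets — no specialised paired-end offset coding, no PPMd/FSE
  backends (role-equivalent stdlib codecs stand in), and heuristics are
  deliberately simple and sequential.
* Quality streams and headers are not compressed; the archive is a
  DNA-stream container only, and decompressed FASTQ carries synthetic
  headers and a constant quality character.
* Hamming-only alignment: indel-containing reads are never mapped and fall
  through to PGlq, inflating archives for indel-rich data.
* The whole read set is held in memory.
* Archive compatibility with any external tool is not claimed; the
  container and dictionary are this package's own versioned formats.
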