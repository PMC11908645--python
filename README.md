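# pgcodec

Lossless, reference-free compression of the **DNA stream** of short-read
FASTQ data (single- or paired-end, plain or gzipped, alphabet
`{A,C,G,T,N}`). Headers and quality strings are not stored — quality is
consulted only to steer the pipeline — so the tool targets the sequence
lines alone, the dominant irreducible component of a FASTQ file.

## Who this is for

Anyone archiving high-coverage resequencing runs who wants substantially
better ratios than general-purpose compressors, delivered by exploiting the
one structure generic codecs cannot see: at coverage *c*, every genomic
position is covered by ~*c* overlapping reads, so the read set is massively
redundant even before entropy coding.

## The method

1. **Read-set division.** Reads containing an N form their own subset.
   Of the rest, a single quality character per read is inspected, at
   distance `⌊0.12·L⌋` from the read's end (index 88 for L=100); if its
   Phred error probability exceeds 63% — Phred ≤ 2, ASCII codes 33/34/35 —
   the read is rejected from the high-quality candidates.
2. **Pseudogenome construction.** The high-quality reads are deduplicated
   and chained by greedy exact suffix–prefix overlaps into *PGhq*, a greedy
   approximation of their shortest common superstring: a single string in
   which every placed read occurs verbatim at a recorded offset. Reads with
   no overlap of at least `min_overlap` (default: half the read length) are
   demoted.
3. **Mismatch-tolerant back-mapping.** Demoted and quality-rejected reads
   are aligned to PGhq with up to `⌊L/M⌋` Hamming mismatches (M=3: 33
   mismatches for L=100), in both orientations, via a sparse-sampled k-mer
   index (k=36, stride 18). A mapped read costs an offset, a strand bit,
   and its mismatch positions/symbols instead of its sequence.
4. **Residual pseudogenomes.** Whatever remains unmapped forms *PGlq*;
   the N-containing reads form *PGN* (same construction, nothing dropped).
5. **Reverse-complement repeat removal.** Long RC repeats inside PGhq
   (≥ 48 bp by default) — redundancy an LZ77-family backend cannot match —
   are excised and replaced by a `%` sentinel plus out-of-band
   (source, length) references.
6. **Variable-length packing.** Pseudogenome texts over `{A,C,G,T,N,%}`
   are packed up to 4 bases per byte with a fixed 242-phrase dictionary
   whose codes are ordered by reversed phrases and whose terminal groups
   start at multiples of 64; the variable phrase lengths let two parses of
   a shared substring re-synchronise, preserving LZ matches through the
   transform.
7. **Multi-stream backend.** Mismatch symbols are rank-coded against
   global order-0 statistics with reference-symbol exclusion (ranks fit in
   `[0,3]`); every stream is then compressed by the best of its candidate
   codecs (LZMA-class only for the packed pseudogenomes; a wider candidate
   set elsewhere) into a checksummed, versioned archive.

Decompression inverts every stage exactly: SE mode restores the read
multiset, the order-preserving modes (`--preserve-order`, paired-end)
restore the exact input order.

## Worked example

Simulate a 20× run over a 20 kb reference (1% substitutions, 0.5% N calls,
half the reads reverse-complemented, 20% low-quality reads), then compress
and restore it:

```python
from pgcodec import SyntheticSpec, generate_synthetic_reads, write_fastq
ss = generate_synthetic_reads(SyntheticSpec(
    ref_length=20_000, coverage=20, read_length=100,
    substitution_rate=0.01, n_rate=0.005, rc_fraction=0.5,
    low_quality_fraction=0.2, seed=1))
write_fastq(ss.reads, "example.fastq")
```

```console
$ pgcodec compress -i example.fastq -o example.pgz --preserve-order
mode SE_ORD: 4000 reads -> 70227 bytes
  pseudogenome placements: 666 HQ, 879 LQ, 1618 N; 828 mapped with mismatches; 117 RC repeats removed
$ pgcodec decompress -i example.pgz -o restored.fastq
mode SE_ORD: restored 4000 reads
```

400,000 input bases compress to 70,227 bytes (≈1.40 bits per base) with the
input order preserved, and `restored.fastq` carries exactly the original
sequences (with synthetic headers and constant quality, which are not
stored). The summary line reads: 666 deduplicated high-quality reads were
placed directly in PGhq, 828 residual reads were encoded as mapped offsets
plus mismatches, 879 went to PGlq and 1,618 N-containing reads to PGN, and
117 reverse-complement repeats were excised from PGhq before packing.

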