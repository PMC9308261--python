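# Methods

## Model and assumptions

`qsarc` compresses the quality stream of FASTQ files (or bare quality-line
files) losslessly, with exact random access to any 1-based inclusive line
range `[a, b]`. It assumes only that quality characters lie in ASCII 33–104
(the union of the Phred+33 and Phred+64 conventions; codes outside this
range are rejected rather than guessed at) and that, as in real sequencing
data, adjacent scores are correlated: long runs of a single value and small
local excursions dominate. Read lengths may vary freely, including empty
lines; nothing downstream assumes a fixed length.

The pipeline has four stages — classification, mapping, indexing, block
compression — each implemented behind its own module boundary
(`classify`, `qmap`, `archive`, `backend`).

### Classification

K-mer statistics are fitted on the first `min(M, n)` lines. For k-mer *j*
with occurrence count `N_j` (overlaps counted) out of `N` total windows,
its proportion is `q̄_j = N_j / N`. Line *l*'s raw feature is
`ē_l = Σ q̄_j` over the *distinct* k-mers present in the line (each counted
once; k-mers unseen in the sample contribute 0; lines shorter than *k*
score 0). The normaliser `L_m = max ē_l` over the sample yields the
clamped feature `Mx = min(1, ē_l / L_m)`; the clamp matters because
out-of-sample lines can exceed the in-sample maximum. Class A is
`Mx > α` strictly — a tie at exactly α goes to class B, a convention fixed
so that decoding never depends on floating-point luck. The in-sample
argmax always has `Mx = 1` exactly (it is divided by itself).

Note that a line consisting solely of one repeated k-mer can never beat
the in-sample maximum (any sample line containing that k-mer scores at
least as much), but a line *tiling* a k-mer accumulates the proportions
of all k rotations; when those rotations never co-occur in a single
sample line the raw ratio exceeds 1. The acceptance corpus for the clamp
is built exactly this way.

Defaults: `k = 4`, `M = 10,000`, `α = 0.5`. `k = 4` is small enough that a
10k-line sample densely populates the table over a ≤72-character alphabet
yet long enough to capture local context; `M = 10,000` keeps fitting
sub-second at any file size; `α = 0.5` is a neutral midpoint. All three
are recorded in the archive header, so decoding never re-derives them.
`k ≤ 10` is enforced so base-72 k-mer codes fit in int64.

### Mapping

Each class is mapped independently, anchored on its own modal score *C*
(most frequent value; ties break to the smallest code for determinism).
The per-class *C* reflects that the two classes have different score
distributions; both anchors are stored in the header. Branches are tried
in the fixed order run > triple > pair > singleton, scanning left to
right — precedence must be fixed for the decode to be deterministic:

| branch  | condition                                  | symbol                                   | range    |
|---------|--------------------------------------------|------------------------------------------|----------|
| run     | `q_i = q_{i+1} = C`, maximal `k ≤ 55`      | `k + 200`                                | 202–255  |
| triple↑ | 3 scores in `[C, C+3]`                     | `16·(C+3−q_i) + 4·(C+3−q_{i+1}) + (C+3−q_{i+2}) + 319` | 319–382 |
| triple↓ | 3 scores in `[C−3, C]`                     | `16·(q_i−C+3) + 4·(q_{i+1}−C+3) + (q_{i+2}−C+3) + 137` | 137–200 |
| pair↑   | 2 scores in `[C, C+7]`, not `(C+7, C+7)`   | `8·(C+7−q_i) + (C+7−q_{i+1}) + 255`      | 256–318  |
| pair↓   | 2 scores in `[C−7, C]`                     | `8·(q_i−C+7) + (q_{i+1}−C+7) + 73`       | 73–136   |
| single  | otherwise                                  | `q_i − 32`                               | 1–72     |

Three corner cases are resolved deliberately. (1) *Collision fix*: a run
of 55 and the pair `(C+7, C+7)` both evaluate to 255; the pair case is
excluded (it falls back to two singletons), so 255 uniquely decodes as a
run — the minimal change that keeps every constant above intact and makes
the branch output ranges pairwise disjoint. (2) A run requires at least
two adjacent copies of *C*; a lone *C* falls through to the other
branches, so symbol 201 is never emitted (the decoder still accepts it as
a run of one). (3) Pairs straddling *C* with one score outside the
one-sided window are not merged — no rule covers them — and become two
singletons. Because of greedy precedence the largest symbol an actual
line can produce is 378 (`(C, C+1, C)` and relatives; the all-modal
triple that would reach 382 is always consumed as a run first), while the
branch formulas top out at 382; both are far inside the 512-value design
bound.

Values 510 and 511 are reserved stream markers (class-B placeholder and
end-of-line); 0 and 383–509 never occur.

### Containers, index, random access

Container A receives, in original line order, each mapped class-A line
terminated by the end-of-line symbol, or a single placeholder symbol per
class-B line; container B receives the mapped class-B lines in order.
Containers are cut into blocks of `block_size` lines (placeholders count
as lines in A, which keeps the line arithmetic uniform), and each block
is compressed independently.

The index holds one entry per block, not per line — that is what keeps
its cost negligible (tens of bytes per 20,000-line block; measured
≈0.01 % of a million-line archive). An A-entry stores the block's first
global line number and the cumulative placeholder count of all preceding
A-blocks; a B-entry stores its first and last class-B ordinal. A range
query binary-searches the A-index for the covering A-blocks, scans their
placeholder flags to convert the global range into a class-B ordinal
range `[a_B, b_B]` (the ordinal of a placeholder is its cumulative count;
placeholders in a contiguous line range have contiguous ordinals), and
binary-searches the B-index for the covering B-blocks. Only those blocks
are decompressed; a per-reader cache guarantees each at most once per
query, and `ArchiveReader.stats` counts backend invocations so tests can
assert the covering-set bound. Full decompression walks all blocks and
interleaves the two containers by placeholder flags, restoring original
order exactly.

### Serialization and archive format

Symbols are escape-coded to bytes before backend compression: values
1–255 as a single byte, 256–511 as `0x00` plus the low byte (0 is never a
symbol, so the escape is unambiguous). A fixed 16-bit encoding was
measured first and roughly doubled the payload seen by the backend,
enough to make the mapped archive *larger* than the raw stream through
the same LZ backend; the escape coding gives the common at-or-below-`C`
half of the alphabet single-byte cost and restored the mapping's benefit
(archive ≈1.03× the raw-stream deflate size on a run-rich corpus, ≤1.00×
under lzma, versus ≈1.16× with fixed 16-bit).

The archive layout is: magic `QSV1`, length-prefixed header (`k`, `M`, α
in micro-units, `C_A`, `C_B`, `block_size`, `n_lines`, backend id, total
score count), the compressed A-blocks then B-blocks, both index tables
(five u64 per entry, including per-block CRC32), and a footer with the
two index offsets and a whole-file CRC32. All integers are little-endian.
The header is sufficient to decode without re-deriving anything; the
total score count is carried so `inspect` can report bits per score
without decompressing. Block compression may run on several threads, but
results are written in block order, so the archive bytes are identical
for any thread count.

### Backends

The entropy-coding backend is a contract (`decode(encode(x)) == x` on
arbitrary bytes), not a contribution: `store`, `deflate` (zlib, default
level 6) and `lzma` (xz, default preset 4) ship always; a `zstd` id is
reserved and registered only when the `zstandard` module is importable.
Context-mixing compressors in the ZPAQ family would likely improve the
rate further but are deliberately not reimplemented. The backend id is
stored in the header; an unknown id on decode is a hard error.

## Synthetic data

The generator (`synthgen`) emulates the two features the pipeline
exploits — small effective alphabets and adjacent-score correlation —
with a first-order Markov chain: each score repeats the previous one with
probability `run_persistence`, otherwise jumps uniformly to another
symbol of the profile's alphabet. Profiles sketch public-archive platform
variety: `illumina_binned` (fixed 100-score reads, 8-value quality
ladder, persistence 0.85), `pacbio_wide` (variable 80–300, wide alphabet,
0.55), `nanopore_long` (variable 200–1,000, mid-width, 0.6) and
`uniform_noise` (full 72-value alphabet, persistence 0 — the adversarial
case). Persistence values are set so that run/pair/triple structure
dominates for instrument-like profiles and vanishes for noise.

What the generator does *not* emulate: position-dependent quality decay
along the read, correlation between quality and base composition,
per-instrument bin placement, and heavy-tailed read-length distributions.
Passing tests therefore demonstrate correctness (losslessness, exact
random access, index arithmetic) on data with realistic run structure,
and qualitative compression behaviour — not the compression rates any
particular instrument would achieve.

## Numerical and degenerate-input choices

- Classification works in exact integer counts; proportions are formed
  once as float64. The only comparisons on floats are `Mx > α` and the
  clamp; the in-sample maximum is exactly 1 by construction.
- An input whose lines are all shorter than *k* has no k-mer evidence;
  every line goes to class B rather than failing.
- Empty files, empty lines, single-class streams (container B empty, or
  container A all placeholders) and single-line files all round-trip.
- The modal score of an empty class falls back to the stream-wide modal
  score (or 33 for an empty stream); it is stored but never used.
- Hot loops (mapping, container parsing, per-line k-mer features,
  container interleaving) are numba kernels over uint8/uint16 arrays; the
  pure-Python rule-by-rule evaluator retained in the test suite acts as
  an independent oracle for them.

## Problem sizes used in the checks

The behavioural test suite exercises six ~50,000-line corpora (fixed and
variable lengths across all four profiles) for round trips and 200 random
range extractions each, a 1,000,000-line corpus for index-overhead and
binary-search/linear-scan equivalence, and 60,000-line corpora for the
block-size/access-cost trend over block sizes 15,000–30,000. These sizes
give stable statistics for every property while keeping a full run of the
suite inside a few minutes on one CPU.

## Known limitations

- Only the quality stream is archived; identifiers and bases are out of
  scope by design, so the FASTQ writer emits placeholder headers/bases.
- The archive format is this package's own; it does not interoperate with
  any other tool's containers.
- `block_size` trades compression rate against random-access cost
  monotonically; there is no auto-tuner.
- Shipping backends are LZ-family; rates on real data would differ under
  a context-mixing backend.
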