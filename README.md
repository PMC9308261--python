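# qsarc — lossless, random-access compression of FASTQ quality scores

Quality scores are the hard part of FASTQ compression: unlike the 4-letter
base alphabet they span up to 71 ASCII values (codes 33–104) with low
redundancy, and they account for the majority of a losslessly compressed
FASTQ file. At the same time, analyses rarely need the whole file — they
need the quality lines for a specific read range, which general-purpose
compressors can only deliver by decompressing everything.

`qsarc` is a Python library (with a thin CLI) for people who store or serve
sequencing data and need both a good compression rate and exact random
access to the quality stream. It works in four stages:

1. **Classification.** A sample of the first *M* quality lines is scanned
   for length-*k* substrings (k-mers over quality characters). Each line
   *l* gets a feature
   `ē_l = Σ_j q̄_j` over its *distinct* k-mers, where `q̄_j = N_j / N` is the
   j-th k-mer's sample proportion, normalised and clamped to
   `Mx = min(1, ē_l / L_m)` with `L_m = max_l ē_l` over the sample.
   Lines with `Mx > α` form class A (high k-mer repetition, good statistics
   for context modelling); the rest form class B.
2. **Mapping.** Within each class, the modal score *C* anchors an
   invertible mapping of adjacent scores onto symbols 1–382: a run of
   `k ≤ 55` copies of *C* becomes the single symbol `k + 200`; triples
   within `[C−3, C+3]` on one side of *C* pack into one symbol
   (`+319` above, `+137` below); pairs within `[C−7, C+7]` on one side pack
   into one symbol (`+255` above, `+73` below); everything else is the
   singleton `q − 32`.
3. **Indexing.** Class-A lines (plus one placeholder per class-B line,
   preserving original order) and class-B lines are cut into blocks of
   `block_size` lines. A per-block index — class A: first global line
   number and cumulative placeholder count; class B: first/last class-B
   ordinal — is searched binarily to find the blocks covering any line
   range `[a, b]`.
4. **Compression.** Each block is compressed independently by a pluggable
   lossless backend (`deflate` default, `lzma`, `store`), so extraction
   decompresses only the covering blocks.

The compression rate is reported as **bits per quality score**
(`8 × archive bytes / number of quality characters`; raw text is 8.0).

## Worked example

```python
from qsarc import compress_archive, inspect_archive, ArchiveReader, synthgen

lines = synthgen.generate(synthgen.profile("illumina_binned", n_reads=20_000, seed=1))
compress_archive(lines, "example.qsv", block_size=5_000)
print(inspect_archive("example.qsv"))
```

prints (see `examples/01_compress_roundtrip.py`):

```
lines compressed:     20000
quality scores:       2000000
archive size:         405364 bytes
bits per score:       1.621  (raw is 8.0)
index overhead:       0.0493% of the archive
round trip identical: True
```

so two million quality characters compress to 1.62 bits each, the
random-access index costs 0.05 % of the archive, and decompression restores
the input byte for byte. Random access touches only the covering blocks
(`examples/02_random_access.py`):

```
requested lines:      [17001, 17100]  (100 lines)
matches the original: True
blocks decompressed:  2 (of 24 in the archive)
```

The other examples show the classification feature in isolation
(`03_classification.py`) and the symbol mapping on a single line
(`04_symbol_mapping.py`). The same pipeline is scriptable from the shell:

```sh
qsarc generate corpus.fastq --profile illumina_binned --n-reads 50000 --seed 1 --format fastq
qsarc compress corpus.fastq corpus.qsv
qsarc extract corpus.qsv --range 1001:1100
qsarc inspect corpus.qsv
```

Note that only the quality stream is archived; read identifiers and base
sequences are out of scope.

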