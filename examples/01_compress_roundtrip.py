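"""Compress a synthetic quality corpus, inspect the archive, and verify
the lossless round trip.

The bits-per-score figure is the compression rate: 8 x archive bytes /
number of quality characters.  The index overhead shows how little the
random-access tables cost.
"""

import tempfile
from pathlib import Path

from qsarc import compress_archive, decompress_archive, inspect_archive, synthgen

tmp = Path(tempfile.mkdtemp())
lines = synthgen.generate(synthgen.profile("illumina_binned", n_reads=20_000, seed=1))
archive = tmp / "example.qsv"

compress_archive(lines, archive, block_size=5_000)
info = inspect_archive(archive)
print(f"lines compressed:     {info['n_lines']}")
print(f"quality scores:       {info['total_scores']}")
print(f"archive size:         {info['archive_bytes']} bytes")
print(f"bits per score:       {info['bits_per_score']:.3f}  (raw is 8.0)")
print(f"index overhead:       {info['index_overhead_pct']:.4f}% of the archive")

back = decompress_archive(archive)
ok = [ql.scores for ql in back] == [ql.scores for ql in lines]
print(f"round trip identical: {ok}")
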