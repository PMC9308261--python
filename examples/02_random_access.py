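"""Extract a small line range from a large archive and count how many
blocks had to be decompressed.

Only the blocks covering the requested range are touched, so the cost of
a 100-line window is a handful of blocks, not the whole file.
"""

import tempfile
from pathlib import Path

from qsarc import ArchiveReader, compress_archive, synthgen

tmp = Path(tempfile.mkdtemp())
lines = synthgen.generate(synthgen.profile("pacbio_wide", n_reads=30_000, seed=2))
archive = tmp / "example.qsv"
compress_archive(lines, archive, block_size=2_000)

reader = ArchiveReader(archive)
a, b = 17_001, 17_100
got = reader.extract(a, b)
match = [ql.scores for ql in got] == [ql.scores for ql in lines[a - 1: b]]

print(f"requested lines:      [{a}, {b}]  ({b - a + 1} lines)")
print(f"matches the original: {match}")
print(f"blocks decompressed:  {reader.stats['blocks_decoded']} "
      f"(of {len(reader.a_index) + len(reader.b_index)} in the archive)")
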