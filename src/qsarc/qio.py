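"""Quality-line I/O.

The compressor operates exclusively on the quality stream of a FASTQ file
(the fourth line of each record), or on a plain text file with one quality
line per row.  Quality characters must lie in the ASCII range 33..104, the
union of the Phred+33 and Phred+64 conventions.  Read lengths may vary
between records; empty lines are legal.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Literal

import numpy as np

QUAL_MIN = 33
QUAL_MAX = 104

Format = Literal["fastq", "lines"]

__all__ = [
    "QUAL_MIN",
    "QUAL_MAX",
    "QualityLine",
    "FormatError",
    "read_quality_stream",
    "write_quality_stream",
    "read_quality_arrays",
    "arrays_to_lines",
    "lines_to_arrays",
]


class FormatError(ValueError):
    """Malformed input: bad FASTQ structure or quality code out of range."""


@dataclass(frozen=True)
class QualityLine:
    """One quality line with its 1-based ordinal in the source file.

    ``scores`` is the raw ASCII string; every code point must lie in
    [33, 104].  ``line_no`` counts quality lines (reads), not file rows.
    """

    line_no: int
    scores: str

    def __post_init__(self) -> None:
        if self.line_no < 1:
            raise ValueError(f"line_no must be >= 1, got {self.line_no}")
        _validate_scores(self.scores, self.line_no)

    def __len__(self) -> int:
        return len(self.scores)


def _validate_scores(scores: str, line_no: int) -> None:
    for ch in scores:
        code = ord(ch)
        if code < QUAL_MIN or code > QUAL_MAX:
            raise FormatError(
                f"quality code {code} outside [{QUAL_MIN}, {QUAL_MAX}] "
                f"at quality line {line_no}"
            )


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="ascii", newline="\n")
    return open(path, mode, encoding="ascii", newline="\n")


def read_quality_stream(path: str | Path, format: Format = "fastq") -> Iterator[QualityLine]:
    """Yield :class:`QualityLine` records from ``path`` in file order.

    ``format="fastq"`` expects 4-line records (identifier, bases,
    separator, qualities) and checks that each quality line matches its
    base line in length; ``format="lines"`` reads one quality line per
    row.  Gzipped files are detected by a ``.gz`` suffix.
    """
    if format == "fastq":
        yield from _read_fastq(path)
    elif format == "lines":
        yield from _read_lines(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_lines(path: str | Path) -> Iterator[QualityLine]:
    with _open_text(path) as fh:
        for i, row in enumerate(fh, start=1):
            yield QualityLine(i, row.rstrip("\n"))


def _read_fastq(path: str | Path) -> Iterator[QualityLine]:
    with _open_text(path) as fh:
        n = 0
        while True:
            header = fh.readline()
            if not header:
                return
            bases = fh.readline()
            sep = fh.readline()
            qual = fh.readline()
            n += 1
            row = 4 * (n - 1) + 1
            if not qual:
                raise FormatError(f"truncated FASTQ record starting at file row {row}")
            if not header.startswith("@"):
                raise FormatError(f"FASTQ identifier at file row {row} does not start with '@'")
            if not sep.startswith("+"):
                raise FormatError(f"FASTQ separator at file row {row + 2} does not start with '+'")
            bases_s = bases.rstrip("\n")
            qual_s = qual.rstrip("\n")
            if len(bases_s) != len(qual_s):
                raise FormatError(
                    f"quality length {len(qual_s)} != base length {len(bases_s)} "
                    f"in record {n} (file row {row})"
                )
            yield QualityLine(n, qual_s)


def write_quality_stream(
    lines: Iterable[QualityLine], path: str | Path, format: Format = "lines"
) -> None:
    """Write quality lines to ``path``.

    ``format="lines"`` is the byte-exact inverse of reading: one line per
    row, LF-terminated.  ``format="fastq"`` emits placeholder records
    (synthetic ``@read_N`` identifiers and ``N`` bases) carrying only the
    quality information -- lossy with respect to original headers/bases.
    """
    with _open_text(path, "wt") as fh:
        if format == "lines":
            for ql in lines:
                fh.write(ql.scores)
                fh.write("\n")
        elif format == "fastq":
            for ql in lines:
                fh.write(f"@read_{ql.line_no}\n")
                fh.write("N" * len(ql.scores))
                fh.write("\n+\n")
                fh.write(ql.scores)
                fh.write("\n")
        else:
            raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Array fast path used by the compression pipeline.  Quality content is held
# as one flat uint8 buffer plus an int64 offsets vector of length n+1; line i
# (0-based) is flat[offsets[i]:offsets[i+1]].


def lines_to_arrays(lines: Iterable[QualityLine]) -> tuple[np.ndarray, np.ndarray]:
    """Pack quality lines into (flat uint8 scores, int64 offsets)."""
    bufs = [ql.scores.encode("ascii") for ql in lines]
    lengths = np.fromiter((len(b) for b in bufs), dtype=np.int64, count=len(bufs))
    offsets = np.zeros(len(bufs) + 1, dtype=np.int64)
    np.cumsum(lengths, out=offsets[1:])
    flat = np.frombuffer(b"".join(bufs), dtype=np.uint8).copy()
    return flat, offsets


def arrays_to_lines(flat: np.ndarray, offsets: np.ndarray) -> list[QualityLine]:
    """Inverse of :func:`lines_to_arrays`, re-numbering from 1."""
    raw = flat.tobytes()
    return [
        QualityLine(i + 1, raw[offsets[i]: offsets[i + 1]].decode("ascii"))
        for i in range(len(offsets) - 1)
    ]


def read_quality_arrays(path: str | Path, format: Format = "fastq") -> tuple[np.ndarray, np.ndarray]:
    """Read a whole file into the flat-array representation.

    Validates the quality alphabet once, vectorised, instead of per
    character; used by ``compress`` so multi-million-line inputs do not
    materialise per-line objects.
    """
    chunks: list[bytes] = []
    lengths: list[int] = []
    if format == "lines":
        with _open_text(path) as fh:
            for row in fh:
                b = row.rstrip("\n").encode("ascii")
                chunks.append(b)
                lengths.append(len(b))
    elif format == "fastq":
        with _open_text(path) as fh:
            n = 0
            while True:
                header = fh.readline()
                if not header:
                    break
                bases = fh.readline()
                sep = fh.readline()
                qual = fh.readline()
                n += 1
                row = 4 * (n - 1) + 1
                if not qual:
                    raise FormatError(f"truncated FASTQ record starting at file row {row}")
                if not header.startswith("@"):
                    raise FormatError(f"FASTQ identifier at file row {row} does not start with '@'")
                if not sep.startswith("+"):
                    raise FormatError(f"FASTQ separator at file row {row + 2} does not start with '+'")
                b = qual.rstrip("\n").encode("ascii")
                if len(bases.rstrip("\n")) != len(b):
                    raise FormatError(
                        f"quality length != base length in record {n} (file row {row})"
                    )
                chunks.append(b)
                lengths.append(len(b))
    else:
        raise ValueError(f"unknown format {format!r}")

    flat = np.frombuffer(b"".join(chunks), dtype=np.uint8).copy()
    offsets = np.zeros(len(chunks) + 1, dtype=np.int64)
    np.cumsum(np.asarray(lengths, dtype=np.int64), out=offsets[1:])
    if flat.size and (flat.min() < QUAL_MIN or flat.max() > QUAL_MAX):
        bad = int(np.argmax((flat < QUAL_MIN) | (flat > QUAL_MAX)))
        line = int(np.searchsorted(offsets, bad, side="right")) - 1
        raise FormatError(
            f"quality code {int(flat[bad])} outside [{QUAL_MIN}, {QUAL_MAX}] "
            f"at quality line {line + 1}"
        )
    return flat, offsets
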