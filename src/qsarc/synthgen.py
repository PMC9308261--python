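"""Seeded synthetic quality-score corpora.

Real quality streams are dominated by two features the compressor
exploits: a small effective alphabet (instrument binning) and strong
adjacent-score correlation (runs).  The generator emulates both with a
first-order Markov chain over a configurable score alphabet: at each
position the previous score repeats with probability ``run_persistence``,
otherwise the next score is drawn uniformly from the rest of the
alphabet.  Read lengths are fixed or uniform in a range.  Everything is
driven by a single seed, so corpora are bit-reproducible.

Built-in profiles sketch the platform variety of public archives:

* ``illumina_binned`` -- short fixed reads, 8 binned scores, long runs
* ``pacbio_wide``     -- long variable reads, wide alphabet, moderate runs
* ``nanopore_long``   -- very long variable reads, mid-width alphabet
* ``uniform_noise``   -- worst case: full alphabet, no correlation
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np

from .qio import QUAL_MAX, QUAL_MIN, QualityLine, arrays_to_lines, write_quality_stream

__all__ = ["GeneratorProfile", "PROFILES", "generate", "generate_arrays", "generate_file"]


@dataclass(frozen=True)
class GeneratorProfile:
    """Parameters of the Markov score process for one synthetic corpus."""

    name: str
    read_length: int | tuple[int, int]
    run_persistence: float
    alphabet: tuple[int, ...]
    n_reads: int
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.read_length, tuple):
            lo, hi = self.read_length
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid read_length range {self.read_length}")
        elif self.read_length < 0:
            raise ValueError("read_length must be >= 0")
        if not 0.0 <= self.run_persistence <= 1.0:
            raise ValueError("run_persistence must lie in [0, 1]")
        if not self.alphabet:
            raise ValueError("alphabet must be nonempty")
        for c in self.alphabet:
            if not QUAL_MIN <= c <= QUAL_MAX:
                raise ValueError(f"alphabet score {c} outside [{QUAL_MIN}, {QUAL_MAX}]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


#: typical Illumina 8-bin quality ladder (Phred+33 codes)
_ILLUMINA_BINS = (35, 41, 47, 53, 58, 64, 70, 73)

PROFILES: dict[str, GeneratorProfile] = {
    "illumina_binned": GeneratorProfile(
        "illumina_binned", 100, 0.85, _ILLUMINA_BINS, 10_000
    ),
    "pacbio_wide": GeneratorProfile(
        "pacbio_wide", (80, 300), 0.55, tuple(range(33, 94)), 5_000
    ),
    "nanopore_long": GeneratorProfile(
        "nanopore_long", (200, 1_000), 0.6, tuple(range(36, 74)), 2_000
    ),
    "uniform_noise": GeneratorProfile(
        "uniform_noise", 100, 0.0, tuple(range(QUAL_MIN, QUAL_MAX + 1)), 10_000
    ),
}


def profile(name: str, **overrides) -> GeneratorProfile:
    """A built-in profile with optional field overrides."""
    return replace(PROFILES[name], **overrides)


def generate_arrays(prof: GeneratorProfile) -> tuple[np.ndarray, np.ndarray]:
    """Generate a corpus as (flat uint8 scores, int64 offsets).

    Vectorised across reads: all chains advance one position per step,
    so run-time scales with the maximum read length, not n_reads times
    length.
    """
    rng = np.random.default_rng(prof.seed)
    n = prof.n_reads
    if isinstance(prof.read_length, tuple):
        lo, hi = prof.read_length
        lengths = rng.integers(lo, hi + 1, size=n).astype(np.int64)
    else:
        lengths = np.full(n, prof.read_length, dtype=np.int64)
    alphabet = np.asarray(prof.alphabet, dtype=np.uint8)
    A = alphabet.size
    maxlen = int(lengths.max()) if n else 0

    # state indices into the alphabet, advanced column by column
    mat = np.zeros((n, maxlen), dtype=np.uint8) if maxlen else np.zeros((n, 0), dtype=np.uint8)
    if maxlen:
        state = rng.integers(0, A, size=n)
        mat[:, 0] = alphabet[state]
        for pos in range(1, maxlen):
            repeat = rng.random(n) < prof.run_persistence
            if A > 1:
                # uniform over the other A-1 symbols
                jump = rng.integers(1, A, size=n)
                state = np.where(repeat, state, (state + jump) % A)
            mat[:, pos] = alphabet[state]
    mask = np.arange(maxlen)[None, :] < lengths[:, None]
    flat = mat[mask]
    offsets = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(lengths, out=offsets[1:])
    return flat, offsets


def generate(prof: GeneratorProfile) -> list[QualityLine]:
    """Generate a corpus as :class:`QualityLine` records."""
    flat, offsets = generate_arrays(prof)
    return arrays_to_lines(flat, offsets)


def generate_file(
    prof: GeneratorProfile,
    path: str | Path,
    format: Literal["fastq", "lines"] = "lines",
) -> None:
    """Generate a corpus and write it as a FASTQ or lines file."""
    write_quality_stream(generate(prof), path, format)
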