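"""Invertible mapping of quality lines onto a compact symbol alphabet.

Adjacent quality scores are strongly correlated: long runs of a single
value and small local excursions dominate real data.  The mapper anchors
on the modal score C of the stream and merges neighbourhoods of C into
single symbols:

* a run of 2..55 consecutive copies of C  -> one symbol ``k + 200``;
* three adjacent scores all within 3 of C (one side) -> one symbol
  (base-4 offsets packed, ``+319`` above C / ``+137`` below);
* two adjacent scores all within 7 of C (one side) -> one symbol
  (base-8 offsets packed, ``+255`` above C / ``+73`` below);
* anything else -> the singleton ``q - 32``.

Branches are tried in that order, scanning left to right, so decoding is
deterministic.  Emitted values live in [1, 382]; 510 and 511 are reserved
stream markers (class-B placeholder, end of line) and 0 is never used.
The pair (C+7, C+7) would collide with the run-of-55 symbol at value 255
and is therefore excluded from the pair branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import _kernels
from ._kernels import EOL, PLACEHOLDER, RUN_CAP
from .qio import QUAL_MAX, QUAL_MIN, QualityLine

#: largest value any mapping branch can emit (run cap 55 -> 255 is interior;
#: the triple-above-C branch tops out at 63 + 319)
MAX_EMITTED = 382

__all__ = [
    "RUN_CAP",
    "EOL",
    "PLACEHOLDER",
    "MAX_EMITTED",
    "MapperParams",
    "SymbolSeq",
    "modal_score",
    "map_line",
    "unmap_line",
    "map_stream",
    "unmap_stream",
]


@dataclass(frozen=True)
class MapperParams:
    """Mapping anchor: the modal quality score C of the stream."""

    C: int
    run_cap: int = RUN_CAP

    def __post_init__(self) -> None:
        if not QUAL_MIN <= self.C <= QUAL_MAX:
            raise ValueError(f"C must lie in [{QUAL_MIN}, {QUAL_MAX}], got {self.C}")
        if self.run_cap != RUN_CAP:
            raise ValueError(f"run_cap is fixed at {RUN_CAP}")


SymbolSeq = np.ndarray  # uint16 vector, values in {0} | [1, 511]


def modal_score(lines: Iterable[QualityLine]) -> int:
    """ASCII code occurring most often over all lines; ties break low."""
    counts = np.zeros(QUAL_MAX + 1, dtype=np.int64)
    any_score = False
    for ql in lines:
        if ql.scores:
            any_score = True
            arr = np.frombuffer(ql.scores.encode("ascii"), dtype=np.uint8)
            counts += np.bincount(arr, minlength=QUAL_MAX + 1)
    if not any_score:
        raise ValueError("cannot take the modal score of an empty stream")
    return int(np.argmax(counts))  # argmax returns the smallest tied index


def modal_score_flat(flat: np.ndarray) -> int:
    """Modal score of a flat uint8 score buffer (ties break low)."""
    if flat.size == 0:
        raise ValueError("cannot take the modal score of an empty stream")
    return int(np.argmax(np.bincount(flat, minlength=QUAL_MAX + 1)))


def map_line(line: QualityLine | str, params: MapperParams) -> SymbolSeq:
    """Map one quality line to its symbol sequence."""
    scores = line.scores if isinstance(line, QualityLine) else line
    arr = np.frombuffer(scores.encode("ascii"), dtype=np.uint8)
    if arr.size and (arr.min() < QUAL_MIN or arr.max() > QUAL_MAX):
        raise ValueError("quality code outside [33, 104]")
    out = np.empty(max(arr.size, 1), dtype=np.uint16)
    n = _kernels.map_line(arr, params.C, out)
    return out[:n].copy()


def unmap_line(symbols: SymbolSeq | Sequence[int], params: MapperParams) -> str:
    """Exact inverse of :func:`map_line` under the same params."""
    sym = np.asarray(symbols, dtype=np.uint16)
    out = np.empty(max(sym.size * RUN_CAP, 1), dtype=np.uint8)
    n = _kernels.unmap_line(sym, params.C, out)
    if n < 0:
        j = -int(n) - 1
        raise ValueError(
            f"symbol {int(sym[j])} at position {j} is reserved or never emitted"
        )
    return out[:n].tobytes().decode("ascii")


def map_stream(lines: Iterable[QualityLine], params: MapperParams) -> SymbolSeq:
    """Concatenate mapped lines, appending the end-of-line marker 511
    after each line so boundaries survive concatenation."""
    parts: list[np.ndarray] = []
    eol = np.array([EOL], dtype=np.uint16)
    for ql in lines:
        parts.append(map_line(ql, params))
        parts.append(eol)
    if not parts:
        return np.empty(0, dtype=np.uint16)
    return np.concatenate(parts)


def unmap_stream(symbols: SymbolSeq, params: MapperParams) -> list[str]:
    """Split on the end-of-line marker and invert each line."""
    sym = np.asarray(symbols, dtype=np.uint16)
    flat, offsets, status = _kernels.parse_container_b(sym, params.C)
    if status < 0:
        if status == -1:
            raise ValueError("symbol stream does not end with an end-of-line marker")
        j = -int(status) - 1
        raise ValueError(f"symbol {int(sym[j])} at position {j} is reserved or never emitted")
    raw = flat.tobytes()
    return [raw[offsets[i]: offsets[i + 1]].decode("ascii") for i in range(offsets.size - 1)]
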