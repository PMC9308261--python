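"""Block-compressed, indexed archive of a quality-score stream.

Layout (all integers little-endian)::

    magic "QSV1" | header_len u32 | header | A-blocks | B-blocks
    | A-index | B-index | footer

    header : k u8, M u32, alpha (micro-units) u32, C_A u8, C_B u8,
             block_size u32, n_lines u64, backend_id u8, total_scores u64
    A-index entry (40 B): first_line u64, cum_placeholders u64,
             byte_offset u64, comp_len u64, checksum u64
    B-index entry (40 B): first_ordinal u64, last_ordinal u64,
             byte_offset u64, comp_len u64, checksum u64
    footer (24 B): A-index offset u64, B-index offset u64, file crc u64

Lines are classified into class A (high k-mer repetition) and class B.
Container A holds, in original line order, each mapped class-A line
(terminated by the end-of-line symbol 511) or one placeholder symbol
(510) per class-B line; container B holds the mapped class-B lines in
order.  Both containers are cut into blocks of ``block_size`` lines
(placeholders count as lines in A), each serialised as escape-coded
symbol bytes (1..255 direct; 256..511 as 0x00 followed by the low byte)
and compressed independently, so any line range can be recovered by
decompressing only the covering blocks.  The per-block index makes the
covering set a binary search; its cumulative-placeholder field converts
a global line number into a class-B ordinal.
"""

from __future__ import annotations

import struct
import zlib
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import _kernels, backend as _backend
from ._kernels import EOL, PLACEHOLDER
from .classify import ClassifierParams, classify_arrays
from .qio import (
    Format,
    QualityLine,
    arrays_to_lines,
    lines_to_arrays,
    read_quality_arrays,
)
from .qmap import MapperParams, modal_score_flat

MAGIC = b"QSV1"
DEFAULT_BLOCK_SIZE = 20_000
_HEADER_FMT = "<BIIBBIQBQ"
_ENTRY_FMT = "<QQQQQ"
_FOOTER_FMT = "<QQQ"
_ENTRY_SIZE = struct.calcsize(_ENTRY_FMT)

__all__ = [
    "DEFAULT_BLOCK_SIZE",
    "AIndexEntry",
    "BIndexEntry",
    "ArchiveHeader",
    "ArchiveError",
    "Containers",
    "ArchiveReader",
    "build_containers",
    "build_index",
    "compress_archive",
    "decompress_archive",
    "extract_range",
    "inspect_archive",
]


class ArchiveError(ValueError):
    """Corrupt or inconsistent archive."""


@dataclass
class AIndexEntry:
    """Index record for one container-A block.

    ``first_line`` is the 1-based global line number of the block's first
    container line; ``cum_placeholders`` counts class-B placeholders in
    all *preceding* A-blocks.
    """

    first_line: int
    cum_placeholders: int
    byte_offset: int = 0
    comp_len: int = 0
    checksum: int = 0


@dataclass
class BIndexEntry:
    """Index record for one container-B block, in class-B ordinals."""

    first_ordinal: int
    last_ordinal: int
    byte_offset: int = 0
    comp_len: int = 0
    checksum: int = 0


@dataclass
class ArchiveHeader:
    k: int
    M: int
    alpha: float
    C_A: int
    C_B: int
    block_size: int
    n_lines: int
    backend: str
    total_scores: int

    def pack(self) -> bytes:
        return struct.pack(
            _HEADER_FMT,
            self.k,
            self.M,
            round(self.alpha * 1_000_000),
            self.C_A,
            self.C_B,
            self.block_size,
            self.n_lines,
            _backend.BackendSpec(self.backend).numeric_id,
            self.total_scores,
        )

    @classmethod
    def unpack(cls, raw: bytes) -> "ArchiveHeader":
        k, M, alpha_u, C_A, C_B, bs, n_lines, bid, total = struct.unpack(
            _HEADER_FMT, raw[: struct.calcsize(_HEADER_FMT)]
        )
        return cls(k, M, alpha_u / 1_000_000, C_A, C_B, bs, n_lines,
                   _backend.backend_id(bid), total)


@dataclass
class Containers:
    """Mapped containers plus the label vector they were built from."""

    a_symbols: np.ndarray       # uint16, one entry per container-A line boundary
    a_line_offsets: np.ndarray  # int64, length n+1 (placeholder = 1 symbol)
    b_symbols: np.ndarray
    b_line_offsets: np.ndarray  # int64, length n_B+1
    labels: np.ndarray          # uint8, 1 = class A

    @property
    def n_lines(self) -> int:
        return int(self.labels.size)

    @property
    def n_b_lines(self) -> int:
        return int(self.b_line_offsets.size - 1)

    @property
    def placeholder_positions(self) -> np.ndarray:
        """1-based global line numbers of the class-B placeholders."""
        return np.flatnonzero(self.labels == 0) + 1


def build_containers(
    labeled: Iterable[tuple[QualityLine, str]] | None = None,
    params_a: MapperParams | None = None,
    params_b: MapperParams | None = None,
    *,
    flat: np.ndarray | None = None,
    offsets: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> Containers:
    """Map labelled lines into containers A and B.

    Accepts either a sequence of ``(QualityLine, "A"|"B")`` pairs or the
    flat-array form (``flat``, ``offsets``, ``labels`` with 1 = A).  The
    number of placeholders in container A always equals the number of
    lines in container B.
    """
    if labeled is not None:
        pairs = list(labeled)
        flat, offsets = lines_to_arrays([ql for ql, _ in pairs])
        labels = np.fromiter(
            (1 if lab == "A" else 0 for _, lab in pairs), dtype=np.uint8, count=len(pairs)
        )
    assert flat is not None and offsets is not None and labels is not None
    if params_a is None or params_b is None:
        raise ValueError("mapper params for both classes are required")
    a_sym, a_off = _kernels.build_container_a(flat, offsets, labels, params_a.C)
    b_sym, b_off = _kernels.build_container_b(flat, offsets, labels, params_b.C)
    return Containers(a_sym, a_off, b_sym, b_off, labels)


def build_index(
    containers: Containers, block_size: int
) -> tuple[list[AIndexEntry], list[BIndexEntry]]:
    """One index entry per block (byte fields filled at write time)."""
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    n = containers.n_lines
    n_b = containers.n_b_lines
    is_ph = (containers.labels == 0).astype(np.int64)
    cum_ph = np.concatenate([[0], np.cumsum(is_ph)])
    a_entries = [
        AIndexEntry(first_line=lo + 1, cum_placeholders=int(cum_ph[lo]))
        for lo in range(0, n, block_size)
    ]
    b_entries = [
        BIndexEntry(first_ordinal=lo + 1, last_ordinal=min(lo + block_size, n_b))
        for lo in range(0, n_b, block_size)
    ]
    return a_entries, b_entries


def _escape_symbols(sym: np.ndarray) -> np.ndarray:
    """Escape-code symbols to bytes: 1..255 as themselves, 256..511 as
    0x00 followed by (value - 256).  0 is never a symbol, so the escape
    byte is unambiguous; most emitted symbols (everything at or below the
    run range) cost a single byte."""
    hi = sym > 255
    out = np.zeros(sym.size + int(hi.sum()), dtype=np.uint8)
    pos = np.zeros(sym.size, dtype=np.int64)
    if sym.size > 1:
        np.cumsum(1 + hi[:-1].astype(np.int64), out=pos[1:])
    out[pos[~hi]] = sym[~hi].astype(np.uint8)
    out[pos[hi] + 1] = (sym[hi] - 256).astype(np.uint8)
    return out


def _unescape_symbols(buf: bytes) -> np.ndarray:
    sym, status = _kernels.unescape_symbols(np.frombuffer(buf, dtype=np.uint8))
    if status < 0:
        raise ArchiveError("dangling escape byte in symbol block")
    return sym


def _block_payloads(
    symbols: np.ndarray, line_offsets: np.ndarray, block_size: int
) -> list[bytes]:
    """Cut a container into per-block escape-coded byte payloads."""
    n = line_offsets.size - 1
    out = []
    for lo in range(0, n, block_size):
        hi = min(lo + block_size, n)
        seg = symbols[line_offsets[lo]: line_offsets[hi]]
        out.append(_escape_symbols(seg).tobytes())
    return out


def compress_archive(
    input_path: str | Path | Sequence[QualityLine],
    output_path: str | Path,
    *,
    format: Format = "fastq",
    k: int = 4,
    sample_lines: int = 10_000,
    alpha: float = 0.5,
    block_size: int = DEFAULT_BLOCK_SIZE,
    backend: str = "deflate",
    level: int | None = None,
    threads: int = 1,
) -> ArchiveHeader:
    """Compress a quality stream into an archive file.

    ``input_path`` may be a FASTQ/lines file path or an in-memory
    sequence of :class:`QualityLine`.  Block compression may use several
    worker threads; the archive bytes are identical for any thread
    count (results are written in block order).
    """
    if isinstance(input_path, (str, Path)):
        flat, offsets = read_quality_arrays(input_path, format)
    else:
        flat, offsets = lines_to_arrays(list(input_path))
    return compress_arrays(
        flat,
        offsets,
        output_path,
        k=k,
        sample_lines=sample_lines,
        alpha=alpha,
        block_size=block_size,
        backend=backend,
        level=level,
        threads=threads,
    )


def compress_arrays(
    flat: np.ndarray,
    offsets: np.ndarray,
    output_path: str | Path,
    *,
    k: int = 4,
    sample_lines: int = 10_000,
    alpha: float = 0.5,
    block_size: int = DEFAULT_BLOCK_SIZE,
    backend: str = "deflate",
    level: int | None = None,
    threads: int = 1,
) -> ArchiveHeader:
    """Array-level compression pipeline (classify, map, pack, index)."""
    n = offsets.size - 1
    params = ClassifierParams(k=k, M=sample_lines, alpha=alpha)
    if n == 0:
        labels = np.empty(0, dtype=np.uint8)
    else:
        try:
            labels, _ = classify_arrays(flat, offsets, params)
        except ValueError:
            # no line long enough for a k-mer: no repetition evidence at all
            labels = np.zeros(n, dtype=np.uint8)

    fallback_c = modal_score_flat(flat) if flat.size else 33
    lengths = np.diff(offsets)
    mask_a = np.repeat(labels == 1, lengths) if n else np.zeros(0, dtype=bool)
    flat_a = flat[mask_a]
    flat_b = flat[~mask_a]
    C_A = modal_score_flat(flat_a) if flat_a.size else fallback_c
    C_B = modal_score_flat(flat_b) if flat_b.size else fallback_c

    containers = build_containers(
        params_a=MapperParams(C_A),
        params_b=MapperParams(C_B),
        flat=flat,
        offsets=offsets,
        labels=labels,
    )
    a_entries, b_entries = build_index(containers, block_size)
    a_payloads = _block_payloads(containers.a_symbols, containers.a_line_offsets, block_size)
    b_payloads = _block_payloads(containers.b_symbols, containers.b_line_offsets, block_size)

    spec = _backend.BackendSpec(backend, level)
    if threads > 1 and len(a_payloads) + len(b_payloads) > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            comp = list(pool.map(lambda p: _backend.encode(p, spec), a_payloads + b_payloads))
    else:
        comp = [_backend.encode(p, spec) for p in a_payloads + b_payloads]
    comp_a, comp_b = comp[: len(a_payloads)], comp[len(a_payloads):]

    header = ArchiveHeader(
        k=k,
        M=sample_lines,
        alpha=alpha,
        C_A=C_A,
        C_B=C_B,
        block_size=block_size,
        n_lines=n,
        backend=spec.id,
        total_scores=int(flat.size),
    )

    crc = 0

    def _w(fh, data: bytes) -> None:
        nonlocal crc
        fh.write(data)
        crc = zlib.crc32(data, crc)

    with open(output_path, "wb") as fh:
        _w(fh, MAGIC)
        hdr = header.pack()
        _w(fh, struct.pack("<I", len(hdr)))
        _w(fh, hdr)
        pos = len(MAGIC) + 4 + len(hdr)
        for entry, blob in zip(a_entries, comp_a):
            entry.byte_offset = pos
            entry.comp_len = len(blob)
            entry.checksum = zlib.crc32(blob)
            _w(fh, blob)
            pos += len(blob)
        for entry, blob in zip(b_entries, comp_b):
            entry.byte_offset = pos
            entry.comp_len = len(blob)
            entry.checksum = zlib.crc32(blob)
            _w(fh, blob)
            pos += len(blob)
        a_index_offset = pos
        for e in a_entries:
            _w(fh, struct.pack(
                _ENTRY_FMT, e.first_line, e.cum_placeholders, e.byte_offset,
                e.comp_len, e.checksum,
            ))
            pos += _ENTRY_SIZE
        b_index_offset = pos
        for e in b_entries:
            _w(fh, struct.pack(
                _ENTRY_FMT, e.first_ordinal, e.last_ordinal, e.byte_offset,
                e.comp_len, e.checksum,
            ))
            pos += _ENTRY_SIZE
        fh.write(struct.pack(_FOOTER_FMT, a_index_offset, b_index_offset, crc))
    return header


@dataclass
class LocateResult:
    """Covering block sets for a line-range query."""

    a_blocks: range
    b_ordinals: tuple[int, int] | None  # class-B ordinal range [a_B, b_B]
    b_blocks: range


def covering_blocks(firsts: np.ndarray, a: int, b: int) -> range:
    """Minimal contiguous block range covering items a..b, given each
    block's first item number (sorted ascending).  Binary search."""
    if firsts.size == 0:
        return range(0)
    lo = int(np.searchsorted(firsts, a, side="right")) - 1
    hi = int(np.searchsorted(firsts, b, side="right")) - 1
    lo = max(lo, 0)
    return range(lo, hi + 1)


class ArchiveReader:
    """Random-access reader over an archive file.

    Decompressed blocks are cached so a query decodes each covering
    block exactly once; ``stats["blocks_decoded"]`` counts backend
    invocations (used to verify the covering-set bound).
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.stats = {"blocks_decoded": 0}
        self._a_cache: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._b_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        with open(self.path, "rb") as fh:
            raw = fh.read()
        self._raw = raw
        if len(raw) < len(MAGIC) + 4 + struct.calcsize(_FOOTER_FMT) or raw[:4] != MAGIC:
            raise ArchiveError("not a quality-score archive (bad magic)")
        (hdr_len,) = struct.unpack_from("<I", raw, 4)
        self.header = ArchiveHeader.unpack(raw[8: 8 + hdr_len])
        a_off, b_off, crc = struct.unpack_from(_FOOTER_FMT, raw, len(raw) - struct.calcsize(_FOOTER_FMT))
        if zlib.crc32(raw[: len(raw) - struct.calcsize(_FOOTER_FMT)]) != crc:
            raise ArchiveError("file checksum mismatch")
        body_end = len(raw) - struct.calcsize(_FOOTER_FMT)
        self.a_index = self._read_entries(raw[a_off:b_off], AIndexEntry)
        self.b_index = self._read_entries(raw[b_off:body_end], BIndexEntry)
        self._a_firsts = np.array([e.first_line for e in self.a_index], dtype=np.int64)
        self._b_firsts = np.array([e.first_ordinal for e in self.b_index], dtype=np.int64)
        self._spec = _backend.BackendSpec(self.header.backend)

    @staticmethod
    def _read_entries(raw: bytes, cls):
        if len(raw) % _ENTRY_SIZE:
            raise ArchiveError("index section length is not a multiple of the entry size")
        return [
            cls(*struct.unpack_from(_ENTRY_FMT, raw, i))
            for i in range(0, len(raw), _ENTRY_SIZE)
        ]

    @property
    def n_lines(self) -> int:
        return self.header.n_lines

    # -- block decoding ---------------------------------------------------

    def _decode_blob(self, byte_offset: int, comp_len: int, checksum: int) -> bytes:
        blob = self._raw[byte_offset: byte_offset + comp_len]
        if zlib.crc32(blob) != checksum:
            raise ArchiveError(f"block checksum mismatch at offset {byte_offset}")
        self.stats["blocks_decoded"] += 1
        return _backend.decode(blob, self._spec)

    def _a_block(self, i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Parsed A-block i: (flat scores, line offsets, placeholder flags)."""
        if i not in self._a_cache:
            e = self.a_index[i]
            sym = _unescape_symbols(self._decode_blob(e.byte_offset, e.comp_len, e.checksum))
            flat, offs, flags, status = _kernels.parse_container_a(sym, self.header.C_A)
            if status < 0:
                raise ArchiveError(f"corrupt symbol stream in A-block {i} (status {status})")
            self._a_cache[i] = (flat, offs, flags)
        return self._a_cache[i]

    def _b_block(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        if j not in self._b_cache:
            e = self.b_index[j]
            sym = _unescape_symbols(self._decode_blob(e.byte_offset, e.comp_len, e.checksum))
            flat, offs, status = _kernels.parse_container_b(sym, self.header.C_B)
            if status < 0:
                raise ArchiveError(f"corrupt symbol stream in B-block {j} (status {status})")
            self._b_cache[j] = (flat, offs)
        return self._b_cache[j]

    def drop_cache(self) -> None:
        """Forget decoded blocks and reset the decode counter (so the
        cost of the next query can be measured in isolation)."""
        self._a_cache.clear()
        self._b_cache.clear()
        self.stats["blocks_decoded"] = 0

    # -- queries ----------------------------------------------------------

    def locate_blocks(self, a: int, b: int) -> LocateResult:
        """Covering A-blocks for lines [a, b]; after scanning them, the
        class-B ordinal range and its covering B-blocks."""
        if a < 1 or b > self.n_lines or a > b:
            raise ValueError(f"invalid range [{a}, {b}] for {self.n_lines} lines")
        a_blocks = covering_blocks(self._a_firsts, a, b)
        a_B = b_B = None
        for i in a_blocks:
            e = self.a_index[i]
            _, _, flags = self._a_block(i)
            lo = max(a, e.first_line) - e.first_line
            hi = min(b, e.first_line + flags.size - 1) - e.first_line
            if hi < lo:
                continue
            ph = np.flatnonzero(flags[lo: hi + 1] == 1)
            if ph.size:
                cum_before = e.cum_placeholders + int(np.sum(flags[:lo]))
                first = cum_before + 1 + int(np.sum(flags[lo: lo + ph[0]]))
                last = cum_before + int(np.sum(flags[lo: hi + 1]))
                if a_B is None:
                    a_B = first
                b_B = last
        if a_B is None:
            return LocateResult(a_blocks, None, range(0))
        return LocateResult(a_blocks, (a_B, b_B), covering_blocks(self._b_firsts, a_B, b_B))

    def extract(self, a: int, b: int) -> list[QualityLine]:
        """Lines a..b, byte-identical to the original stream, decoding
        only the covering blocks."""
        loc = self.locate_blocks(a, b)
        b_lines: list[bytes] = []
        if loc.b_ordinals is not None:
            a_B, b_B = loc.b_ordinals
            for j in loc.b_blocks:
                e = self.b_index[j]
                flat, offs = self._b_block(j)
                raw = flat.tobytes()
                lo = max(a_B, e.first_ordinal) - e.first_ordinal
                hi = min(b_B, e.last_ordinal) - e.first_ordinal
                for t in range(lo, hi + 1):
                    b_lines.append(raw[offs[t]: offs[t + 1]])
        out: list[QualityLine] = []
        bi = 0
        for i in loc.a_blocks:
            e = self.a_index[i]
            flat, offs, flags = self._a_block(i)
            raw = flat.tobytes()
            lo = max(a, e.first_line) - e.first_line
            hi = min(b, e.first_line + flags.size - 1) - e.first_line
            for t in range(lo, hi + 1):
                g = e.first_line + t
                if flags[t] == 1:
                    out.append(QualityLine(g, b_lines[bi].decode("ascii")))
                    bi += 1
                else:
                    out.append(QualityLine(g, raw[offs[t]: offs[t + 1]].decode("ascii")))
        return out

    def decompress_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Full decompression to the flat-array representation."""
        a_parts, a_off_parts, flag_parts = [], [], []
        base = 0
        for i in range(len(self.a_index)):
            flat, offs, flags = self._a_block(i)
            a_parts.append(flat)
            a_off_parts.append(offs[:-1] + base)
            flag_parts.append(flags)
            base += int(offs[-1])
        b_parts, b_off_parts = [], []
        bbase = 0
        for j in range(len(self.b_index)):
            flat, offs = self._b_block(j)
            b_parts.append(flat)
            b_off_parts.append(offs[:-1] + bbase)
            bbase += int(offs[-1])
        a_flat = np.concatenate(a_parts) if a_parts else np.empty(0, dtype=np.uint8)
        a_offsets = np.concatenate(a_off_parts + [np.array([base], dtype=np.int64)])
        flags = (
            np.concatenate(flag_parts) if flag_parts else np.empty(0, dtype=np.uint8)
        )
        b_flat = np.concatenate(b_parts) if b_parts else np.empty(0, dtype=np.uint8)
        b_offsets = np.concatenate(b_off_parts + [np.array([bbase], dtype=np.int64)])
        if flags.size != self.n_lines:
            raise ArchiveError(
                f"decoded {flags.size} container lines, header says {self.n_lines}"
            )
        if int(np.sum(flags)) != b_offsets.size - 1:
            raise ArchiveError("placeholder count does not match container-B line count")
        return _kernels.merge_containers(a_flat, a_offsets, flags, b_flat, b_offsets)

    def decompress(self) -> list[QualityLine]:
        flat, offsets = self.decompress_arrays()
        return arrays_to_lines(flat, offsets)

    # -- accounting -------------------------------------------------------

    def inspect(self) -> dict:
        """Archive accounting: sizes, block counts, index overhead and the
        compression-rate metric (bits per quality score)."""
        archive_bytes = len(self._raw)
        index_bytes = (len(self.a_index) + len(self.b_index)) * _ENTRY_SIZE
        h = self.header
        return {
            "n_lines": h.n_lines,
            "total_scores": h.total_scores,
            "n_a_blocks": len(self.a_index),
            "n_b_blocks": len(self.b_index),
            "block_size": h.block_size,
            "backend": h.backend,
            "k": h.k,
            "sample_lines": h.M,
            "alpha": h.alpha,
            "C_A": h.C_A,
            "C_B": h.C_B,
            "archive_bytes": archive_bytes,
            "index_bytes": index_bytes,
            "index_overhead_pct": 100.0 * index_bytes / archive_bytes if archive_bytes else 0.0,
            "bits_per_score": 8.0 * archive_bytes / h.total_scores if h.total_scores else float("inf"),
        }


def decompress_archive(archive_path: str | Path) -> list[QualityLine]:
    """Lossless inverse of :func:`compress_archive`."""
    return ArchiveReader(archive_path).decompress()


def extract_range(archive_path: str | Path, a: int, b: int) -> list[QualityLine]:
    """Extract lines [a, b] (1-based, inclusive) without full decompression."""
    return ArchiveReader(archive_path).extract(a, b)


def inspect_archive(archive_path: str | Path) -> dict:
    return ArchiveReader(archive_path).inspect()
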