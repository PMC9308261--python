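"""Pluggable lossless byte-stream backends for block compression.

The preprocessing stages (classification, mapping, indexing) are backend
agnostic: any codec satisfying ``decode(encode(x)) == x`` on arbitrary
byte strings can close the pipeline.  Shipped backends:

* ``store``   -- identity; useful for debugging and as a speed baseline
* ``deflate`` -- stdlib zlib (default; fast, decent ratios)
* ``lzma``    -- stdlib LZMA; slower, stronger context modelling
* ``zstd``    -- registered only when the ``zstandard`` module is present

The backend id and level are recorded in the archive header; decoding an
archive whose backend is unknown to this build is a hard error.
"""

from __future__ import annotations

import lzma
import zlib
from dataclasses import dataclass

__all__ = ["BackendSpec", "BackendError", "encode", "decode", "available_backends", "backend_id"]

_IDS = {"store": 0, "deflate": 1, "lzma": 2, "zstd": 3}
_NAMES = {v: k for k, v in _IDS.items()}

_DEFAULT_LEVELS = {"store": 0, "deflate": 6, "lzma": 4, "zstd": 6}


class BackendError(ValueError):
    """Unknown backend id or corrupt compressed data."""


@dataclass(frozen=True)
class BackendSpec:
    """Codec selection: name plus effort level (codec-specific scale)."""

    id: str = "deflate"
    level: int | None = None

    def __post_init__(self) -> None:
        if self.id not in _IDS:
            raise BackendError(f"unknown backend {self.id!r}; known: {sorted(_IDS)}")
        if self.level is None:
            object.__setattr__(self, "level", _DEFAULT_LEVELS[self.id])

    @property
    def numeric_id(self) -> int:
        return _IDS[self.id]


def backend_id(name_or_id: str | int) -> str:
    """Normalise a backend name or wire id to the canonical name."""
    if isinstance(name_or_id, int):
        if name_or_id not in _NAMES:
            raise BackendError(f"unknown backend id {name_or_id}")
        return _NAMES[name_or_id]
    if name_or_id not in _IDS:
        raise BackendError(f"unknown backend {name_or_id!r}")
    return name_or_id


def available_backends() -> list[str]:
    out = ["store", "deflate", "lzma"]
    try:  # optional; not part of the guaranteed environment
        import zstandard  # noqa: F401

        out.append("zstd")
    except ImportError:
        pass
    return out


def encode(data: bytes, spec: BackendSpec) -> bytes:
    """Compress one block; deterministic for fixed (data, spec)."""
    if spec.id == "store":
        return bytes(data)
    if spec.id == "deflate":
        return zlib.compress(data, spec.level)
    if spec.id == "lzma":
        return lzma.compress(
            data, format=lzma.FORMAT_XZ, preset=spec.level, check=lzma.CHECK_CRC32
        )
    if spec.id == "zstd":
        import zstandard

        return zstandard.ZstdCompressor(level=spec.level).compress(data)
    raise BackendError(f"unknown backend {spec.id!r}")


def decode(data: bytes, spec: BackendSpec) -> bytes:
    """Exact inverse of :func:`encode` under the same spec."""
    try:
        if spec.id == "store":
            return bytes(data)
        if spec.id == "deflate":
            return zlib.decompress(data)
        if spec.id == "lzma":
            return lzma.decompress(data)
        if spec.id == "zstd":
            import zstandard

            return zstandard.ZstdDecompressor().decompress(data)
    except (zlib.error, lzma.LZMAError) as exc:
        raise BackendError(f"corrupt {spec.id} block: {exc}") from exc
    raise BackendError(f"unknown backend {spec.id!r}")
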