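"""K-mer statistical classification of quality lines.

Quality lines whose k-mers recur often in a sample taken from the head of
the file (by default the first M lines) tend to share statistical
structure that a context-modelling entropy coder exploits well.  Each line
gets a feature

    e_bar(l) = sum over the DISTINCT k-mers of line l of their sample
               proportion q_j = N_j / N,

normalised by the in-sample maximum L_m and clamped,

    Mx(l) = min(1, e_bar(l) / L_m),

and is assigned to class A (high k-mer repetition) when Mx > alpha,
otherwise class B.  Out-of-sample lines can exceed L_m, which is why the
clamp exists; within the sample the maximising line has Mx = 1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from . import _kernels
from .qio import QualityLine, lines_to_arrays

DEFAULT_K = 4
DEFAULT_SAMPLE_LINES = 10_000
DEFAULT_ALPHA = 0.5

#: largest k for which base-72 k-mer codes fit in int64
MAX_K = 10

Label = Literal["A", "B"]

__all__ = [
    "DEFAULT_K",
    "DEFAULT_SAMPLE_LINES",
    "DEFAULT_ALPHA",
    "KmerModel",
    "ClassifierParams",
    "LineFeature",
    "fit_kmer_model",
    "fit_kmer_model_arrays",
    "line_feature",
    "classify_stream",
    "classify_arrays",
]


@dataclass
class KmerModel:
    """Occurrence statistics of length-k quality substrings in a sample.

    ``counts`` maps each k-mer (as a string) to its occurrence count,
    overlaps included; ``proportions`` holds the count divided by the
    total number of k-mer occurrences.
    """

    k: int
    counts: dict[str, int]
    total: int = field(init=False)

    def __post_init__(self) -> None:
        self.total = sum(self.counts.values())
        # sorted code/proportion arrays for the compiled batch kernel
        codes = np.fromiter(
            (_kmer_code(s) for s in self.counts), dtype=np.int64, count=len(self.counts)
        )
        cnts = np.fromiter(self.counts.values(), dtype=np.int64, count=len(self.counts))
        order = np.argsort(codes)
        self._codes = codes[order]
        self._props = cnts[order] / self.total if self.total else cnts[order].astype(float)

    @property
    def proportions(self) -> dict[str, float]:
        return {s: c / self.total for s, c in self.counts.items()}


@dataclass
class ClassifierParams:
    """Classifier configuration plus the fitted normaliser L_m."""

    k: int = DEFAULT_K
    M: int = DEFAULT_SAMPLE_LINES
    alpha: float = DEFAULT_ALPHA
    L_m: float | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > MAX_K:
            raise ValueError(f"k must be <= {MAX_K}")
        if self.M < 1:
            raise ValueError("sample size M must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")


@dataclass(frozen=True)
class LineFeature:
    """Per-line classification feature: raw e_bar, clamped Mx, label."""

    e_bar: float
    mx: float
    label: Label | None = None


def _kmer_code(kmer: str) -> int:
    code = 0
    for ch in kmer:
        code = code * _kernels.ALPHABET_BASE + (ord(ch) - 33)
    return code


def fit_kmer_model(sample: Sequence[QualityLine], k: int) -> KmerModel:
    """Count all overlapping length-k substrings over the sample lines.

    Lines shorter than k contribute nothing; it is an error for *every*
    sample line to be shorter than k (no evidence to fit on).
    """
    if not sample:
        raise ValueError("sample must be nonempty")
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    for ql in sample:
        s = ql.scores
        for i in range(len(s) - k + 1):
            kmer = s[i: i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
    if not counts:
        raise ValueError(f"no sample line has length >= k={k}")
    return KmerModel(k=k, counts=counts)


def fit_kmer_model_arrays(flat: np.ndarray, offsets: np.ndarray, k: int) -> KmerModel:
    """Array fast path of :func:`fit_kmer_model` (same statistics)."""
    if offsets.size < 2:
        raise ValueError("sample must be nonempty")
    codes = _kernels.collect_kmer_codes(flat, offsets, k)
    if codes.size == 0:
        raise ValueError(f"no sample line has length >= k={k}")
    uniq, cnts = np.unique(codes, return_counts=True)
    model = KmerModel.__new__(KmerModel)
    model.k = k
    model.total = int(codes.size)
    model._codes = uniq
    model._props = cnts / codes.size
    model.counts = _LazyCounts(uniq, cnts, k)  # type: ignore[assignment]
    return model


class _LazyCounts(dict):
    """Dict facade over code/count arrays, materialised on first access."""

    def __init__(self, codes: np.ndarray, cnts: np.ndarray, k: int):
        super().__init__()
        self._codes, self._cnts, self._k, self._built = codes, cnts, k, False

    def _build(self) -> None:
        if self._built:
            return
        base = _kernels.ALPHABET_BASE
        for code, c in zip(self._codes.tolist(), self._cnts.tolist()):
            digits = []
            for _ in range(self._k):
                digits.append(chr(code % base + 33))
                code //= base
            super().__setitem__("".join(reversed(digits)), c)
        self._built = True

    def __getitem__(self, key):  # pragma: no cover - convenience
        self._build()
        return super().__getitem__(key)

    def __iter__(self):
        self._build()
        return super().__iter__()

    def __len__(self):
        return int(self._codes.size)

    def values(self):
        return self._cnts.tolist()

    def items(self):
        self._build()
        return super().items()


def line_feature(line: QualityLine, model: KmerModel, L_m: float) -> LineFeature:
    """Feature of one line: distinct-k-mer proportion sum, clamped ratio.

    Each distinct k-mer is counted once regardless of how often it occurs
    in the line; k-mers absent from the sample contribute 0.  A line
    shorter than k gets e_bar = 0.
    """
    if L_m <= 0:
        raise ValueError("L_m must be > 0")
    k = model.k
    s = line.scores
    seen: set[str] = set()
    e_bar = 0.0
    props = model.proportions if not isinstance(model.counts, _LazyCounts) else None
    for i in range(len(s) - k + 1):
        kmer = s[i: i + k]
        if kmer in seen:
            continue
        seen.add(kmer)
        if props is not None:
            e_bar += props.get(kmer, 0.0)
        else:
            idx = int(np.searchsorted(model._codes, _kmer_code(kmer)))
            if idx < model._codes.size and model._codes[idx] == _kmer_code(kmer):
                e_bar += float(model._props[idx])
    return LineFeature(e_bar=e_bar, mx=min(1.0, e_bar / L_m))


def classify_stream(
    lines: Iterable[QualityLine], params: ClassifierParams
) -> list[tuple[QualityLine, LineFeature]]:
    """Fit on the first min(M, n) lines, then label every line.

    A line is class A iff its clamped feature satisfies ``mx > alpha``
    (strict; ties go to B).  ``params.L_m`` is filled in with the
    in-sample maximum of e_bar.
    """
    lines = list(lines)
    if not lines:
        raise ValueError("stream must be nonempty")
    flat, offsets = lines_to_arrays(lines)
    labels, features = classify_arrays(flat, offsets, params)
    return [
        (ql, LineFeature(e_bar=float(e), mx=float(m), label="A" if lab else "B"))
        for ql, e, m, lab in zip(lines, features["e_bar"], features["mx"], labels)
    ]


def classify_arrays(
    flat: np.ndarray, offsets: np.ndarray, params: ClassifierParams
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Vectorised classification over the flat-array representation.

    Returns ``(labels, features)`` where labels is uint8 (1 = class A)
    and features carries the per-line ``e_bar`` and clamped ``mx``
    arrays.  Side effect: stores the fitted L_m on ``params``.
    """
    n = offsets.size - 1
    if n < 1:
        raise ValueError("stream must be nonempty")
    m = min(params.M, n)
    model = fit_kmer_model_arrays(flat[: offsets[m]], offsets[: m + 1], params.k)
    e_bar = _kernels.line_ebar_batch(flat, offsets, params.k, model._codes, model._props)
    L_m = float(e_bar[:m].max())
    if L_m <= 0:
        raise ValueError("in-sample maximum feature is 0; cannot normalise")
    params.L_m = L_m
    mx = np.minimum(1.0, e_bar / L_m)
    labels = (mx > params.alpha).astype(np.uint8)
    return labels, {"e_bar": e_bar, "mx": mx}
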