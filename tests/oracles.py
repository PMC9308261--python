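"""Independent brute-force reference implementations used as test oracles.

Deliberately naive and kept separate from the package: per-branch rule
evaluation for the mapper, substring counting plus set sums for the
classifier, and linear scans for the block index.
"""

from __future__ import annotations

import math

RUN_CAP = 55


def map_line_oracle(scores: str, C: int) -> list[int]:
    """Greedy rule evaluation, branch by branch, straight off the rules."""
    q = [ord(ch) for ch in scores]
    out: list[int] = []
    i, n = 0, len(q)
    while i < n:
        if q[i] == C and i + 1 < n and q[i + 1] == C:
            k = 0
            while i + k < n and q[i + k] == C and k < RUN_CAP:
                k += 1
            out.append(k + 200)
            i += k
            continue
        if i + 2 < n and all(C <= x <= C + 3 for x in q[i: i + 3]):
            a, b, c = q[i: i + 3]
            out.append(((C + 3) - a) * 16 + ((C + 3) - b) * 4 + ((C + 3) - c) + 319)
            i += 3
            continue
        if i + 2 < n and all(C - 3 <= x <= C for x in q[i: i + 3]):
            a, b, c = q[i: i + 3]
            out.append((a - (C - 3)) * 16 + (b - (C - 3)) * 4 + (c - (C - 3)) + 137)
            i += 3
            continue
        if (
            i + 1 < n
            and all(C <= x <= C + 7 for x in q[i: i + 2])
            and not (q[i] == C + 7 and q[i + 1] == C + 7)
        ):
            a, b = q[i: i + 2]
            out.append(((C + 7) - a) * 8 + ((C + 7) - b) + 255)
            i += 2
            continue
        if i + 1 < n and all(C - 7 <= x <= C for x in q[i: i + 2]):
            a, b = q[i: i + 2]
            out.append((a - (C - 7)) * 8 + (b - (C - 7)) + 73)
            i += 2
            continue
        out.append(q[i] - 32)
        i += 1
    return out


def branch_emissions(C: int, lo: int = 33, hi: int = 104) -> dict[str, set[int]]:
    """Every value each rule branch can emit for anchor C (valid scores only)."""
    runs = {k + 200 for k in range(2, RUN_CAP + 1)}
    pair_hi = {
        ((C + 7) - a) * 8 + ((C + 7) - b) + 255
        for a in range(max(lo, C), min(hi, C + 7) + 1)
        for b in range(max(lo, C), min(hi, C + 7) + 1)
        if not (a == C + 7 and b == C + 7)
    }
    pair_lo = {
        (a - (C - 7)) * 8 + (b - (C - 7)) + 73
        for a in range(max(lo, C - 7), min(hi, C) + 1)
        for b in range(max(lo, C - 7), min(hi, C) + 1)
    }
    tri_hi = {
        ((C + 3) - a) * 16 + ((C + 3) - b) * 4 + ((C + 3) - c) + 319
        for a in range(max(lo, C), min(hi, C + 3) + 1)
        for b in range(max(lo, C), min(hi, C + 3) + 1)
        for c in range(max(lo, C), min(hi, C + 3) + 1)
    }
    tri_lo = {
        (a - (C - 3)) * 16 + (b - (C - 3)) * 4 + (c - (C - 3)) + 137
        for a in range(max(lo, C - 3), min(hi, C) + 1)
        for b in range(max(lo, C - 3), min(hi, C) + 1)
        for c in range(max(lo, C - 3), min(hi, C) + 1)
    }
    singles = {q - 32 for q in range(lo, hi + 1)}
    return {
        "run": runs,
        "pair_high": pair_hi,
        "pair_low": pair_lo,
        "triple_high": tri_hi,
        "triple_low": tri_lo,
        "singleton": singles,
    }


def kmer_counts_oracle(lines: list[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for s in lines:
        for i in range(len(s) - k + 1):
            counts[s[i: i + k]] = counts.get(s[i: i + k], 0) + 1
    return counts


def ebar_oracle(line: str, counts: dict[str, int], k: int) -> float:
    total = sum(counts.values())
    distinct = {line[i: i + k] for i in range(len(line) - k + 1)}
    return sum(counts.get(m, 0) / total for m in distinct)


def classify_oracle(lines: list[str], k: int, M: int, alpha: float):
    """Labels and clamped features by the naive path."""
    sample = lines[: min(M, len(lines))]
    counts = kmer_counts_oracle(sample, k)
    ebars = [ebar_oracle(s, counts, k) for s in lines]
    L_m = max(ebars[: len(sample)])
    mx = [min(1.0, e / L_m) for e in ebars]
    labels = ["A" if m > alpha else "B" for m in mx]
    return labels, mx, L_m


def covering_blocks_oracle(firsts: list[int], n_items: int, a: int, b: int) -> list[int]:
    """Linear scan: block i covers [firsts[i], next first - 1]."""
    out = []
    for i, f in enumerate(firsts):
        last = (firsts[i + 1] - 1) if i + 1 < len(firsts) else n_items
        if f <= b and last >= a:
            out.append(i)
    return out


def ceil_div(a: int, b: int) -> int:
    return math.ceil(a / b)
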