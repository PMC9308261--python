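"""Compiled hot loops (numba) shared by classify, qmap and archive.

All kernels operate on the flat-array representation: quality scores as a
single uint8 buffer plus an int64 offsets vector (line i is
``flat[offsets[i]:offsets[i+1]]``), mapped symbols as uint16.

Symbol layout (C is the modal quality score of the stream being mapped):

====================  =========================================
range                 meaning
====================  =========================================
1..72                 singleton, score = s + 32
73..136               pair, both scores in [C-7, C]
137..200              triple, all scores in [C-3, C]
201..255              run of (s - 200) copies of C
256..318              pair, both scores in [C, C+7]
319..382              triple, all scores in [C, C+3]
510                   class-B placeholder (container A only)
511                   end-of-line marker
====================  =========================================

Value 255 would be emitted both by a run of 55 and by the pair (C+7, C+7);
the pair branch excludes that single case (two singletons instead) so 255
uniquely decodes as a run.
"""

from __future__ import annotations

import numpy as np
from numba import njit

RUN_CAP = 55
PLACEHOLDER = 510
EOL = 511
ALPHABET_BASE = 72  # quality codes 33..104 -> digits 0..71


@njit(cache=True)
def map_line(scores, C, out):
    """Map one quality line into ``out``; returns the symbol count.

    Greedy left-to-right scan with branch precedence
    run > triple > pair > singleton.  ``out`` must have room for
    ``len(scores)`` symbols (all-singleton worst case).
    """
    n = scores.shape[0]
    i = 0
    m = 0
    while i < n:
        a = np.int64(scores[i])
        # run of C (needs at least two adjacent copies)
        if a == C and i + 1 < n and np.int64(scores[i + 1]) == C:
            k = 0
            while i + k < n and np.int64(scores[i + k]) == C and k < RUN_CAP:
                k += 1
            out[m] = np.uint16(k + 200)
            m += 1
            i += k
            continue
        if i + 2 < n:
            b = np.int64(scores[i + 1])
            c = np.int64(scores[i + 2])
            if C <= a <= C + 3 and C <= b <= C + 3 and C <= c <= C + 3:
                out[m] = np.uint16((C + 3 - a) * 16 + (C + 3 - b) * 4 + (C + 3 - c) + 319)
                m += 1
                i += 3
                continue
            if C - 3 <= a <= C and C - 3 <= b <= C and C - 3 <= c <= C:
                out[m] = np.uint16((a - (C - 3)) * 16 + (b - (C - 3)) * 4 + (c - (C - 3)) + 137)
                m += 1
                i += 3
                continue
        if i + 1 < n:
            b = np.int64(scores[i + 1])
            # (C+7, C+7) excluded: its value 255 is reserved for a run of 55
            if C <= a <= C + 7 and C <= b <= C + 7 and not (a == C + 7 and b == C + 7):
                out[m] = np.uint16((C + 7 - a) * 8 + (C + 7 - b) + 255)
                m += 1
                i += 2
                continue
            if C - 7 <= a <= C and C - 7 <= b <= C:
                out[m] = np.uint16((a - (C - 7)) * 8 + (b - (C - 7)) + 73)
                m += 1
                i += 2
                continue
        out[m] = np.uint16(a - 32)
        m += 1
        i += 1
    return m


@njit(cache=True)
def unmap_line(symbols, C, out):
    """Inverse of :func:`map_line`; returns the score count.

    Returns ``-(j + 1)`` if ``symbols[j]`` is outside every emittable
    range (reserved or never-emitted value).  ``out`` needs room for
    ``RUN_CAP * len(symbols)`` scores.
    """
    m = 0
    for j in range(symbols.shape[0]):
        s = np.int64(symbols[j])
        if 1 <= s <= 72:
            out[m] = np.uint8(s + 32)
            m += 1
        elif 73 <= s <= 136:
            v = s - 73
            out[m] = np.uint8(C - 7 + v // 8)
            out[m + 1] = np.uint8(C - 7 + v % 8)
            m += 2
        elif 137 <= s <= 200:
            v = s - 137
            out[m] = np.uint8(C - 3 + v // 16)
            out[m + 1] = np.uint8(C - 3 + (v // 4) % 4)
            out[m + 2] = np.uint8(C - 3 + v % 4)
            m += 3
        elif 201 <= s <= 255:
            for _ in range(s - 200):
                out[m] = np.uint8(C)
                m += 1
        elif 256 <= s <= 318:
            v = s - 255
            out[m] = np.uint8(C + 7 - v // 8)
            out[m + 1] = np.uint8(C + 7 - v % 8)
            m += 2
        elif 319 <= s <= 382:
            v = s - 319
            out[m] = np.uint8(C + 3 - v // 16)
            out[m + 1] = np.uint8(C + 3 - (v // 4) % 4)
            out[m + 2] = np.uint8(C + 3 - v % 4)
            m += 3
        else:
            return -(j + 1)
    return m


@njit(cache=True)
def build_container_a(flat, offsets, labels, C_A):
    """Serialise container A: mapped class-A lines (EOL-terminated) and one
    placeholder symbol per class-B line, in original line order.

    Returns ``(symbols, sym_offsets)`` where ``sym_offsets[i]`` is the
    symbol index at which container-line i starts (length n+1); a
    placeholder occupies exactly one symbol.
    """
    n = offsets.shape[0] - 1
    cap = np.int64(flat.shape[0] + n)  # worst case: all singletons + EOL/placeholder
    out = np.empty(cap, dtype=np.uint16)
    sym_offsets = np.empty(n + 1, dtype=np.int64)
    m = np.int64(0)
    for i in range(n):
        sym_offsets[i] = m
        if labels[i] == 1:
            cnt = map_line(flat[offsets[i]: offsets[i + 1]], C_A, out[m:])
            m += cnt
            out[m] = EOL
            m += 1
        else:
            out[m] = PLACEHOLDER
            m += 1
    sym_offsets[n] = m
    return out[:m].copy(), sym_offsets


@njit(cache=True)
def build_container_b(flat, offsets, labels, C_B):
    """Serialise container B: mapped class-B lines in order, EOL-terminated.

    Returns ``(symbols, sym_offsets)`` with one offset per class-B line
    (length n_B + 1).
    """
    n = offsets.shape[0] - 1
    n_b = np.int64(0)
    for i in range(n):
        if labels[i] == 0:
            n_b += 1
    cap = np.int64(flat.shape[0] + n_b)
    out = np.empty(cap, dtype=np.uint16)
    sym_offsets = np.empty(n_b + 1, dtype=np.int64)
    m = np.int64(0)
    j = 0
    for i in range(n):
        if labels[i] == 0:
            sym_offsets[j] = m
            cnt = map_line(flat[offsets[i]: offsets[i + 1]], C_B, out[m:])
            m += cnt
            out[m] = EOL
            m += 1
            j += 1
    sym_offsets[n_b] = m
    return out[:m].copy(), sym_offsets


@njit(cache=True)
def parse_container_a(symbols, C_A):
    """Decode a container-A symbol block back to lines.

    Returns ``(flat, offsets, is_placeholder, status)``; placeholder lines
    are zero-length with flag 1.  ``status`` is 0 on success, -1 on a
    truncated final line (no EOL), or ``-(j+1)`` for a bad symbol at j.
    """
    ns = symbols.shape[0]
    flat = np.empty(ns * RUN_CAP, dtype=np.uint8)
    offsets = np.empty(ns + 1, dtype=np.int64)
    flags = np.empty(ns, dtype=np.uint8)
    nline = 0
    m = np.int64(0)
    offsets[0] = 0
    i = 0
    while i < ns:
        if symbols[i] == PLACEHOLDER:
            flags[nline] = 1
            nline += 1
            offsets[nline] = m
            i += 1
            continue
        j = i
        while j < ns and symbols[j] != EOL:
            if symbols[j] == PLACEHOLDER:
                return flat[:0], offsets[:1], flags[:0], np.int64(-(j + 1))
            j += 1
        if j == ns:
            return flat[:0], offsets[:1], flags[:0], np.int64(-1)
        cnt = unmap_line(symbols[i:j], C_A, flat[m:])
        if cnt < 0:
            return flat[:0], offsets[:1], flags[:0], np.int64(cnt - i)
        m += cnt
        flags[nline] = 0
        nline += 1
        offsets[nline] = m
        i = j + 1
    return flat[:m].copy(), offsets[: nline + 1].copy(), flags[:nline].copy(), np.int64(0)


@njit(cache=True)
def parse_container_b(symbols, C_B):
    """Decode a container-B symbol block; returns (flat, offsets, status)."""
    ns = symbols.shape[0]
    flat = np.empty(ns * RUN_CAP, dtype=np.uint8)
    offsets = np.empty(ns + 1, dtype=np.int64)
    nline = 0
    m = np.int64(0)
    offsets[0] = 0
    i = 0
    while i < ns:
        j = i
        while j < ns and symbols[j] != EOL:
            j += 1
        if j == ns:
            return flat[:0], offsets[:1], np.int64(-1)
        cnt = unmap_line(symbols[i:j], C_B, flat[m:])
        if cnt < 0:
            return flat[:0], offsets[:1], np.int64(cnt - i)
        m += cnt
        nline += 1
        offsets[nline] = m
        i = j + 1
    return flat[:m].copy(), offsets[: nline + 1].copy(), np.int64(0)


@njit(cache=True)
def unescape_symbols(buf):
    """Decode the escape-coded symbol byte stream: a nonzero byte is the
    symbol itself; 0x00 prefixes (value - 256) for symbols 256..511.

    Returns (symbols uint16, status); status -1 marks a dangling escape.
    """
    n = buf.shape[0]
    out = np.empty(n, dtype=np.uint16)
    m = np.int64(0)
    i = 0
    while i < n:
        b = buf[i]
        if b == 0:
            if i + 1 >= n:
                return out[:0], np.int64(-1)
            out[m] = np.uint16(256 + np.int64(buf[i + 1]))
            m += 1
            i += 2
        else:
            out[m] = np.uint16(b)
            m += 1
            i += 1
    return out[:m].copy(), np.int64(0)


@njit(cache=True)
def merge_containers(a_flat, a_offsets, flags, b_flat, b_offsets):
    """Interleave decoded container-A lines and container-B lines back
    into original order.  ``flags[i] = 1`` marks a placeholder (class-B)
    position; B lines are consumed in ordinal order.

    Returns (flat, offsets) over all n lines.
    """
    n = a_offsets.shape[0] - 1
    total = np.int64(a_flat.shape[0] + b_flat.shape[0])
    out = np.empty(total, dtype=np.uint8)
    offsets = np.empty(n + 1, dtype=np.int64)
    offsets[0] = 0
    m = np.int64(0)
    j = 0
    for i in range(n):
        if flags[i] == 1:
            for t in range(b_offsets[j], b_offsets[j + 1]):
                out[m] = b_flat[t]
                m += 1
            j += 1
        else:
            for t in range(a_offsets[i], a_offsets[i + 1]):
                out[m] = a_flat[t]
                m += 1
        offsets[i + 1] = m
    return out[:m], offsets


# ---------------------------------------------------------------------------
# classification kernels


@njit(cache=True)
def collect_kmer_codes(flat, offsets, k):
    """All overlapping k-mer codes (base-72 integers) over all lines."""
    n = offsets.shape[0] - 1
    total = np.int64(0)
    for i in range(n):
        L = offsets[i + 1] - offsets[i]
        if L >= k:
            total += L - k + 1
    codes = np.empty(total, dtype=np.int64)
    p = np.int64(1)
    for _ in range(k - 1):
        p *= ALPHABET_BASE
    m = np.int64(0)
    for i in range(n):
        s = offsets[i]
        L = offsets[i + 1] - s
        if L < k:
            continue
        code = np.int64(0)
        for j in range(k):
            code = code * ALPHABET_BASE + (np.int64(flat[s + j]) - 33)
        codes[m] = code
        m += 1
        for j in range(1, L - k + 1):
            code = (code - (np.int64(flat[s + j - 1]) - 33) * p) * ALPHABET_BASE + (
                np.int64(flat[s + j + k - 1]) - 33
            )
            codes[m] = code
            m += 1
    return codes


@njit(cache=True)
def line_ebar_batch(flat, offsets, k, uniq_codes, props):
    """Per-line sum of sample proportions over the line's DISTINCT k-mers.

    ``uniq_codes`` must be sorted ascending; a k-mer absent from the
    sample contributes 0.  Lines shorter than k get 0.
    """
    n = offsets.shape[0] - 1
    out = np.zeros(n, dtype=np.float64)
    maxw = np.int64(0)
    for i in range(n):
        w = offsets[i + 1] - offsets[i] - k + 1
        if w > maxw:
            maxw = w
    if maxw <= 0:
        return out
    buf = np.empty(maxw, dtype=np.int64)
    p = np.int64(1)
    for _ in range(k - 1):
        p *= ALPHABET_BASE
    J = uniq_codes.shape[0]
    for i in range(n):
        s = offsets[i]
        L = offsets[i + 1] - s
        if L < k:
            continue
        w = L - k + 1
        code = np.int64(0)
        for j in range(k):
            code = code * ALPHABET_BASE + (np.int64(flat[s + j]) - 33)
        buf[0] = code
        for j in range(1, w):
            code = (code - (np.int64(flat[s + j - 1]) - 33) * p) * ALPHABET_BASE + (
                np.int64(flat[s + j + k - 1]) - 33
            )
            buf[j] = code
        sub = np.sort(buf[:w])
        acc = 0.0
        prev = np.int64(-1)
        for j in range(w):
            c = sub[j]
            if c == prev:
                continue
            prev = c
            lo = 0
            hi = J
            while lo < hi:
                mid = (lo + hi) // 2
                if uniq_codes[mid] < c:
                    lo = mid + 1
                else:
                    hi = mid
            if lo < J and uniq_codes[lo] == c:
                acc += props[lo]
        out[i] = acc
    return out
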