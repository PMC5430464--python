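"""Edit-distance alignment kernels.

Two primitives back every read-level comparison in the package:

``locate``
    semi-global alignment (query global, text free at both ends), used to
    find anchor and junction probes inside a read;
``banded_distance``
    banded global edit distance, used to score a read's shufflon core
    against each candidate arrangement sequence.

Both are unit-cost Levenshtein kernels compiled with numba; indel-dominated
long-read errors make unit costs adequate and keep the band analysis simple.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_INF = np.int32(1 << 29)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array of ASCII codes (uppercased)."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


@njit(cache=True)
def _semiglobal_end(q, t):  # pragma: no cover - exercised via locate()
    """Best edit distance of q against any substring of t ending at j.

    Returns (distance, end) where end is the smallest text offset attaining
    the minimum (deterministic tie-break).
    """
    m = q.shape[0]
    n = t.shape[0]
    prev = np.zeros(n + 1, dtype=np.int32)
    cur = np.empty(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        cur[0] = i
        qa = q[i - 1]
        for j in range(1, n + 1):
            best = prev[j - 1] + (0 if t[j - 1] == qa else 1)
            d = prev[j] + 1
            if d < best:
                best = d
            e = cur[j - 1] + 1
            if e < best:
                best = e
            cur[j] = best
        prev, cur = cur, prev
    best = prev[0]
    end = 0
    for j in range(1, n + 1):
        if prev[j] < best:
            best = prev[j]
            end = j
    return best, end


@njit(cache=True)
def _banded_global(a, b, band):  # pragma: no cover - exercised via wrapper
    m = a.shape[0]
    n = b.shape[0]
    if band < abs(n - m):
        band = abs(n - m)
    prev = np.full(n + 1, _INF, dtype=np.int32)
    cur = np.full(n + 1, _INF, dtype=np.int32)
    hi0 = band if band < n else n
    for j in range(hi0 + 1):
        prev[j] = j
    if hi0 < n:
        prev[hi0 + 1] = _INF
    for i in range(1, m + 1):
        lo = i - band
        if lo < 1:
            lo = 1
        hi = i + band
        if hi > n:
            hi = n
        if lo == 1:
            cur[0] = i
        else:
            cur[lo - 1] = _INF
        ai = a[i - 1]
        for j in range(lo, hi + 1):
            best = prev[j - 1] + (0 if b[j - 1] == ai else 1)
            d = prev[j] + 1
            if d < best:
                best = d
            e = cur[j - 1] + 1
            if e < best:
                best = e
            cur[j] = best
        if hi < n:
            cur[hi + 1] = _INF
        tmp = prev
        prev = cur
        cur = tmp
    return prev[n]


def banded_distance(a: str | np.ndarray, b: str | np.ndarray, band: int | None = None) -> int:
    """Global edit distance between a and b within a diagonal band.

    The band is widened to at least ``|len(a)-len(b)|`` so the result is
    always finite; with ``band=None`` a quarter of the longer sequence is
    used, which comfortably covers the indel drift of PacBio-like error
    rates (net ~5% length drift).
    """
    qa = encode(a) if isinstance(a, str) else a
    qb = encode(b) if isinstance(b, str) else b
    if band is None:
        band = max(32, max(qa.size, qb.size) // 4)
    if qa.size == 0:
        return qb.size
    if qb.size == 0:
        return qa.size
    return int(_banded_global(qa, qb, np.int64(band)))


def locate(query: str | np.ndarray, text: str | np.ndarray) -> tuple[int, int, int]:
    """Find the best semi-global placement of query inside text.

    Returns ``(start, end, distance)`` for the leftmost optimal placement;
    the query aligns end-to-end, the text contributes a substring
    ``text[start:end]``.
    """
    q = encode(query) if isinstance(query, str) else query
    t = encode(text) if isinstance(text, str) else text
    if q.size == 0:
        raise ValueError("empty query")
    if t.size == 0:
        return 0, 0, int(q.size)
    dist, end = _semiglobal_end(q, t)
    # run backwards over the matched prefix to recover the start offset
    _, rev_end = _semiglobal_end(q[::-1].copy(), t[:end][::-1].copy())
    start = end - rev_end
    return int(start), int(end), int(dist)


def identity(query_len: int, other_len: int, distance: int) -> float:
    """Identity proxy: 1 - d / max(len); in [0, 1] for unit-cost distances."""
    denom = max(query_len, other_len)
    if denom == 0:
        return 1.0
    return 1.0 - distance / denom
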