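"""Independent brute-force local-alignment oracle for the test suite.

A top-down memoised three-state dynamic program, written without numpy and
without the scan trick the engine uses, but with the same deterministic
tie-breaking (start at the highest-scoring cell with the smallest (row,
column); prefer diagonal over up over left; close gaps before extending
them). Suitable only for short sequences.
"""

from __future__ import annotations

import sys
from functools import lru_cache

NEG = -1e30


def oracle_align(q: str, s: str, score_fn, gap_open: float, gap_extend: float):
    """Return (score, aligned_q, aligned_s) of the optimal local alignment,
    or None if the optimum is <= 0. ``score_fn(a, b)`` scores a residue pair."""
    m, n = len(q), len(s)
    sys.setrecursionlimit(10000)

    @lru_cache(maxsize=None)
    def M(i, j):  # alignment ending in a match/mismatch at (i, j)
        if i == 0 or j == 0:
            return NEG
        return H(i - 1, j - 1) + score_fn(q[i - 1], s[j - 1])

    @lru_cache(maxsize=None)
    def U(i, j):  # ending in a gap in the subject ("up" move)
        if i == 0:
            return NEG
        return max(H(i - 1, j) - gap_open, U(i - 1, j) - gap_extend)

    @lru_cache(maxsize=None)
    def L(i, j):  # ending in a gap in the query ("left" move)
        if j == 0:
            return NEG
        return max(H(i, j - 1) - gap_open, L(i, j - 1) - gap_extend)

    @lru_cache(maxsize=None)
    def H(i, j):
        return max(0.0, M(i, j), U(i, j), L(i, j))

    best, bi, bj = 0.0, 0, 0
    for i in range(m + 1):
        for j in range(n + 1):
            if H(i, j) > best:
                best, bi, bj = H(i, j), i, j
    if best <= 0:
        return None

    aq, asub = [], []
    i, j, state = bi, bj, "H"
    while True:
        if state == "H":
            v = H(i, j)
            if v == 0:
                break
            if v == M(i, j):
                aq.append(q[i - 1])
                asub.append(s[j - 1])
                i, j = i - 1, j - 1
            elif v == U(i, j):
                state = "U"
            else:
                state = "L"
        elif state == "U":
            aq.append(q[i - 1])
            asub.append("-")
            if U(i, j) == H(i - 1, j) - gap_open:
                state = "H"
            i -= 1
        else:
            aq.append("-")
            asub.append(s[j - 1])
            if L(i, j) == H(i, j - 1) - gap_open:
                state = "H"
            j -= 1
    return best, "".join(reversed(aq)), "".join(reversed(asub))
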