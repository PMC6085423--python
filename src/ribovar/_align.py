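"""Gotoh global alignment with affine gaps (banded, numba-accelerated).

A gap of length k costs ``gap_open + (k-1) * gap_extend`` (both negative).
Tie-breaking is deterministic: at equal score, a match/mismatch column is
preferred over a gap in the query, which is preferred over a gap in the
reference; the same ordering applies to state predecessors.  Determinism
matters because consensus building and locus partitioning both run on the
single optimal alignment returned here.

The DP is banded around the main diagonal for speed (clones differ from the
reference almost entirely by substitutions) and stored band-compressed.
Exactness is preserved: any path leaving a band of half-width w must spend
at least ``2*(w+1)`` gap columns beyond those forced by the length
difference, which bounds its score from above; if the banded optimum beats
that bound it is the global optimum, otherwise the band is widened and the
alignment recomputed, up to the full matrix.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1e30

# traceback ops
_DIAG = 0  # consume ref + qry
_UP = 1    # consume ref only (gap in query)
_LEFT = 2  # consume qry only (gap in reference)


@njit(cache=True)
def _gotoh_fill(a, b, match, mismatch, gap_open, gap_extend, w):  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    # band on the offset j - i: [lo, hi]; stored column k = (j - i) - lo
    lo = min(0, m - n) - w
    hi = max(0, m - n) + w
    W = hi - lo + 1
    M = np.full((n + 1, W), NEG_INF, dtype=np.float64)
    X = np.full((n + 1, W), NEG_INF, dtype=np.float64)  # gap in query (up)
    Y = np.full((n + 1, W), NEG_INF, dtype=np.float64)  # gap in reference (left)
    pM = np.zeros((n + 1, W), dtype=np.int8)
    pX = np.zeros((n + 1, W), dtype=np.int8)
    pY = np.zeros((n + 1, W), dtype=np.int8)

    M[0, -lo] = 0.0
    for i in range(1, n + 1):
        if -i < lo:
            break
        X[i, -i - lo] = gap_open + (i - 1) * gap_extend
        pX[i, -i - lo] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        if j > hi:
            break
        Y[0, j - lo] = gap_open + (j - 1) * gap_extend
        pY[0, j - lo] = 2 if j > 1 else 0

    for i in range(1, n + 1):
        jlo = max(1, i + lo)
        jhi = min(m, i + hi)
        for j in range(jlo, jhi + 1):
            k = j - i - lo        # this cell
            # neighbours in band coordinates:
            # (i-1, j-1) -> row i-1, col k ; (i-1, j) -> col k+1 ; (i, j-1) -> col k-1
            s = match if a[i - 1] == b[j - 1] else mismatch
            # preference at equal score: M > X > Y
            best = M[i - 1, k]
            arg = 0
            if X[i - 1, k] > best:
                best = X[i - 1, k]
                arg = 1
            if Y[i - 1, k] > best:
                best = Y[i - 1, k]
                arg = 2
            M[i, k] = best + s
            pM[i, k] = arg

            if k + 1 < W:
                best = M[i - 1, k + 1] + gap_open
                arg = 0
                if X[i - 1, k + 1] + gap_extend > best:
                    best = X[i - 1, k + 1] + gap_extend
                    arg = 1
                if Y[i - 1, k + 1] + gap_open > best:
                    best = Y[i - 1, k + 1] + gap_open
                    arg = 2
                X[i, k] = best
                pX[i, k] = arg

            if k - 1 >= 0:
                best = M[i, k - 1] + gap_open
                arg = 0
                if X[i, k - 1] + gap_open > best:
                    best = X[i, k - 1] + gap_open
                    arg = 1
                if Y[i, k - 1] + gap_extend > best:
                    best = Y[i, k - 1] + gap_extend
                    arg = 2
                Y[i, k] = best
                pY[i, k] = arg

    ops = np.empty(n + m, dtype=np.int8)
    nops = 0
    state = 0
    kend = m - n - lo
    score = M[n, kend]
    if X[n, kend] > score:
        score = X[n, kend]
        state = 1
    if Y[n, kend] > score:
        score = Y[n, kend]
        state = 2
    i, j = n, m
    while i > 0 or j > 0:
        k = j - i - lo
        if state == 0:
            ops[nops] = _DIAG
            prev = pM[i, k]
            i -= 1
            j -= 1
        elif state == 1:
            ops[nops] = _UP
            prev = pX[i, k]
            i -= 1
        else:
            ops[nops] = _LEFT
            prev = pY[i, k]
            j -= 1
        nops += 1
        state = prev
    return ops[:nops][::-1].copy(), score


def _out_of_band_bound(n, m, w, match, gap_open, gap_extend):
    """Upper bound on the score of any path leaving the band of half-width w."""
    delta = abs(n - m)
    g_min = delta + 2 * (w + 1)  # minimum gap columns of an out-of-band path
    if g_min > n + m:
        return NEG_INF
    pairs = (n + m - g_min) // 2
    # gap cost: every gap column pays at least |extend|, at least one gap open
    gap_cost = g_min * (-gap_extend) + (-gap_open + gap_extend)
    return pairs * max(match, 0.0) - gap_cost


def gotoh_global(ref: str, qry: str, match: float, mismatch: float,
                 gap_open: float, gap_extend: float):
    """Align two strings globally; returns (aligned_ref, aligned_qry, score)."""
    a = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(qry.encode("ascii"), dtype=np.uint8)
    n, m = len(a), len(b)
    w = 16
    while True:
        ops, score = _gotoh_fill(
            a, b, float(match), float(mismatch), float(gap_open),
            float(gap_extend), w,
        )
        full = w >= max(n, m)
        if full or score >= _out_of_band_bound(n, m, w, match, gap_open, gap_extend):
            break
        w *= 4
    out_r = []
    out_q = []
    i = j = 0
    for op in ops:
        if op == _DIAG:
            out_r.append(ref[i])
            out_q.append(qry[j])
            i += 1
            j += 1
        elif op == _UP:
            out_r.append(ref[i])
            out_q.append("-")
            i += 1
        else:
            out_r.append("-")
            out_q.append(qry[j])
            j += 1
    return "".join(out_r), "".join(out_q), float(score)
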