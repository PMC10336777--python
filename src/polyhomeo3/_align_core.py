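"""Numba kernels for local alignment.

Two scoring schemes are used in the package:

- the read mapper scores with match +1 / mismatch -1 and a linear gap
  penalty of -2 per gap base (small indels only, as expected between a read
  and its own locus);
- transcript homology search scores with match +1 / mismatch -1 and an
  affine gap of -2 for the first gap base and -1 for each extension,
  computed inside a diagonal band (homeologs are near-globally colinear).

Both kernels are score-only dynamic programming; the mapper recovers
alignment start coordinates by re-running the kernel on reversed sequences.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# base encoding: A=0 C=1 G=2 T=3, anything else 4 (always a mismatch)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def sw_best(read: np.ndarray, ref: np.ndarray, match: int, mismatch: int, gap: int):
    """Smith-Waterman with linear gap penalty; returns (score, qend, rend).

    ``qend``/``rend`` are 1-based end coordinates of the first-encountered
    optimal cell (row-major scan order, hence deterministic).
    """
    n = read.shape[0]
    m = ref.shape[0]
    prev = np.zeros(m + 1, dtype=np.int32)
    cur = np.zeros(m + 1, dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        cur[0] = 0
        ri = read[i - 1]
        for j in range(1, m + 1):
            s = match if (ri == ref[j - 1] and ri != 4) else mismatch
            h = prev[j - 1] + s
            t = prev[j] + gap
            if t > h:
                h = t
            t = cur[j - 1] + gap
            if t > h:
                h = t
            if h < 0:
                h = 0
            cur[j] = h
            if h > best:
                best = h
                bi = i
                bj = j
        prev, cur = cur, prev
    return best, bi, bj


@njit(cache=True)
def banded_affine_score(
    a: np.ndarray,
    b: np.ndarray,
    band: int,
    match: int,
    mismatch: int,
    gap_open: int,
    gap_extend: int,
) -> int:
    """Best local alignment score within a diagonal band |j - i| <= band.

    Affine gaps: the first gap base costs ``gap_open``, each additional base
    ``gap_extend`` (both given as positive penalties).
    """
    n = a.shape[0]
    m = b.shape[0]
    width = 2 * band + 1
    neg = np.int32(-1_000_000)
    h_prev = np.full(width, neg, dtype=np.int32)
    f_prev = np.full(width, neg, dtype=np.int32)
    h_cur = np.full(width, neg, dtype=np.int32)
    f_cur = np.full(width, neg, dtype=np.int32)
    # row 0: H(0, j) = 0 for j within band
    for o in range(width):
        j = 0 + (o - band)
        if 0 <= j <= m:
            h_prev[o] = 0
    best = 0
    for i in range(1, n + 1):
        e = neg  # gap in b (left moves), tracked along the row
        for o in range(width):
            j = i + (o - band)
            if j < 1 or j > m:
                h_cur[o] = neg
                f_cur[o] = neg
                if j == 0:
                    h_cur[o] = 0
                continue
            # F: gap in a (up move): from (i-1, j) = prev row offset o+1
            f = neg
            if o + 1 < width:
                if h_prev[o + 1] > neg:
                    f = h_prev[o + 1] - gap_open
                if f_prev[o + 1] - gap_extend > f:
                    f = f_prev[o + 1] - gap_extend
            # E: gap in b (left move): from (i, j-1) = same row offset o-1
            if o - 1 >= 0:
                e_new = neg
                if h_cur[o - 1] > neg:
                    e_new = h_cur[o - 1] - gap_open
                if e - gap_extend > e_new:
                    e_new = e - gap_extend
                e = e_new
            else:
                e = neg
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != 4) else mismatch
            diag = h_prev[o] + s if h_prev[o] > neg else neg
            h = 0
            if diag > h:
                h = diag
            if f > h:
                h = f
            if e > h:
                h = e
            h_cur[o] = h
            f_cur[o] = f
            if h > best:
                best = h
        h_prev, h_cur = h_cur, h_prev
        f_prev, f_cur = f_cur, f_prev
    return best
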