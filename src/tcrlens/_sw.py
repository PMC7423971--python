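"""Numba kernels for local pairwise alignment (Gotoh affine-gap DP).

Scoring convention: a gap of length L costs ``gap_open + (L - 1) * gap_extend``
(both negative); the first gapped base pays ``gap_open``. All scores are
integers. Sequences are uint8 arrays of base codes (A=0, C=1, G=2, T=3).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**9)

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into base codes; raises on non-ACGT characters."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = _ENCODE[raw]
    if (out == 255).any():
        bad = seq[int(np.argmax(out == 255))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return out


@njit(cache=True)
def sw_score(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Score-only local alignment; O(m) memory, rolling rows."""
    n, m = len(q), len(t)
    H = np.zeros(m + 1, np.int64)
    F = np.full(m + 1, NEG, np.int64)
    best = 0
    for i in range(n):
        qi = q[i]
        e = NEG
        h_left = 0
        for j in range(1, m + 1):
            s = match if qi == t[j - 1] else mismatch
            ee = e + gap_extend
            eo = h_left + gap_open
            e = ee if ee > eo else eo
            ff = F[j] + gap_extend
            fo = H[j] + gap_open
            f = ff if ff > fo else fo
            h = H[j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[j - 1] = h_left
            h_left = h
            F[j] = f
            if h > best:
                best = h
        H[m] = h_left
    return best


@njit(cache=True)
def sw_score_multi(q, flat, offsets, match, mismatch, gap_open, gap_extend, out):  # pragma: no cover
    """Score ``q`` against every segment packed in ``flat``/``offsets``."""
    for k in range(len(offsets) - 1):
        out[k] = sw_score(q, flat[offsets[k] : offsets[k + 1]], match, mismatch, gap_open, gap_extend)


@njit(cache=True)
def sw_traceback(q, t, match, mismatch, gap_open, gap_extend, qpos_of_tpos):  # pragma: no cover
    """Full DP with traceback.

    Fills ``qpos_of_tpos`` (len(t), int64, set to -1) with, for every target
    position matched diagonally on the optimal path, the query position it is
    aligned to. Returns (score, q_start, q_end, t_start, t_end), 0-based
    half-open. The DP optimum is unique in score; among co-optimal paths the
    end cell is the first maximum in row-major order and the traceback prefers
    diagonal > gap-in-target-consuming > gap-in-query-consuming moves.
    """
    n, m = len(q), len(t)
    H = np.zeros((n + 1, m + 1), np.int64)
    E = np.full((n + 1, m + 1), NEG, np.int64)
    F = np.full((n + 1, m + 1), NEG, np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            s = match if qi == t[j - 1] else mismatch
            e = max(E[i, j - 1] + gap_extend, H[i, j - 1] + gap_open)
            f = max(F[i - 1, j] + gap_extend, H[i - 1, j] + gap_open)
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            if h > best:
                best = h
                bi = i
                bj = j
    if best == 0:
        return 0, 0, 0, 0, 0
    i, j = bi, bj
    state = 0  # 0=H, 1=E (gap consumes t), 2=F (gap consumes q)
    while True:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            s = match if q[i - 1] == t[j - 1] else mismatch
            if h == H[i - 1, j - 1] + s:
                qpos_of_tpos[j - 1] = i - 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            if E[i, j] == H[i, j - 1] + gap_open:
                state = 0
            j -= 1
        else:
            if F[i, j] == H[i - 1, j] + gap_open:
                state = 0
            i -= 1
    return best, i, bi, j, bj
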