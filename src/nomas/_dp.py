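"""Numba kernels for the color-coding dynamic program.

Table layout (one table per coloring and per optimization direction):

* ``present[T, u]``  — entry (colorset T, anchor u) holds a subnetwork
* ``entV[T, u]``     — log-rank numerator V of that subnetwork's split
* ``entm1[T, u]``    — number of samples it mutates
* ``entbits[T, u]``  — packed sample indicator (63 payload bits per int64
  word; the sign bit is never used, so all bit ops stay in signed space)
* ``verts[T, u]``    — sorted vertex indices, first popcount(T) slots valid

Candidates for (T, u) combine W(Q, u) with W(R, v) for neighbors v, where
Q contains u's color and R = T \\ Q.  Because V is linear in the sample
indicator, V(union) = V(Q-entry) + V(R-entry) − V(overlap): only the set
bits of the AND of the two bitsets are visited, so one candidate costs
O(words + overlap) instead of O(m).
"""

from __future__ import annotations

import numpy as np
from numba import njit

WORD_BITS = 63  # payload bits per int64 word

_POP16 = np.array([bin(i).count("1") for i in range(1 << 16)], dtype=np.int64)


@njit(cache=False, inline="always")
def _popcnt64(x, tab):
    # x is a non-negative int64
    return (tab[x & 0xFFFF] + tab[(x >> 16) & 0xFFFF]
            + tab[(x >> 32) & 0xFFFF] + tab[(x >> 48) & 0xFFFF])


@njit(cache=False, inline="always")
def _merge_sorted(a, sa, b, sb, out):
    i = 0
    j = 0
    o = 0
    while i < sa and j < sb:
        if a[i] < b[j]:
            out[o] = a[i]
            i += 1
        else:
            out[o] = b[j]
            j += 1
        o += 1
    while i < sa:
        out[o] = a[i]
        i += 1
        o += 1
    while j < sb:
        out[o] = b[j]
        j += 1
        o += 1


@njit(cache=False, inline="always")
def _lex_less(a, b, n):
    for i in range(n):
        if a[i] != b[i]:
            return a[i] < b[i]
    return False


@njit(cache=False, nogil=True)
def fill_group(masks, cols, colors, indptr, indices,
               present, entV, entm1, entbits, verts,
               bpad, m, sign, tab, counter):
    """Fill all (T, u) entries for T in ``masks`` (one colorset-group),
    u in ``cols``.  Reads only entries of strictly smaller colorsets, so
    concurrent calls on disjoint column sets are race-free."""
    Wd = entbits.shape[2]
    k = verts.shape[2]
    cand_verts = np.empty(k, np.int32)
    best_verts = np.empty(k, np.int32)
    n_eval = 0
    for mi in range(masks.shape[0]):
        T = masks[mi]
        szT = _popcnt64(T, tab)
        for ci in range(cols.shape[0]):
            u = cols[ci]
            cub = np.int64(1) << colors[u]
            if T & cub == 0:
                continue
            rem = T & ~cub
            found = False
            best = 0.0
            bQ = np.int64(0)
            bv = -1
            bV = 0.0
            bm1 = 0
            qp = (rem - 1) & rem  # submasks of rem, excluding rem itself
            while True:
                Q = cub | qp
                R = T & ~Q
                if present[Q, u]:
                    VQ = entV[Q, u]
                    m1Q = entm1[Q, u]
                    szQ = _popcnt64(Q, tab)
                    for ei in range(indptr[u], indptr[u + 1]):
                        v = indices[ei]
                        if not present[R, v]:
                            continue
                        n_eval += 1
                        Vand = 0.0
                        cm1 = m1Q + entm1[R, v]
                        for wd in range(Wd):
                            aw = entbits[Q, u, wd] & entbits[R, v, wd]
                            if aw != 0:
                                base = wd * WORD_BITS
                                while aw != 0:
                                    low = aw & (-aw)
                                    Vand += bpad[base + _popcnt64(low - 1, tab)]
                                    cm1 -= 1
                                    aw ^= low
                        V = VQ + entV[R, v] - Vand
                        if cm1 == 0 or cm1 == m:
                            score = 0.0
                        else:
                            score = sign * V / np.sqrt(cm1 * (m - cm1))
                        take = False
                        if not found or score > best:
                            take = True
                        elif score == best:
                            # tie: keep lexicographically smallest vertex set
                            _merge_sorted(verts[Q, u], szQ,
                                          verts[R, v], szT - szQ, cand_verts)
                            if _lex_less(cand_verts, best_verts, szT):
                                take = True
                        if take:
                            found = True
                            best = score
                            bQ = Q
                            bv = v
                            bV = V
                            bm1 = cm1
                            _merge_sorted(verts[Q, u], szQ,
                                          verts[R, v], szT - szQ, best_verts)
                if qp == 0:
                    break
                qp = (qp - 1) & rem
            if found:
                bR = T & ~bQ
                present[T, u] = 1
                entV[T, u] = bV
                entm1[T, u] = bm1
                for wd in range(Wd):
                    entbits[T, u, wd] = entbits[bQ, u, wd] | entbits[bR, bv, wd]
                for i in range(szT):
                    verts[T, u, i] = best_verts[i]
    counter[0] += n_eval


@njit(cache=False, nogil=True)
def fill_group_additive(masks, cols, colors, indptr, indices,
                        present, entA, verts, tab, counter):
    """Additive-score variant: entry score a(S) = sum of per-gene scores.

    Colorfulness makes the combined vertex sets disjoint, so the candidate
    score is simply a(Q-entry) + a(R-entry); each colorful optimum is found
    exactly per coloring."""
    k = verts.shape[2]
    cand_verts = np.empty(k, np.int32)
    best_verts = np.empty(k, np.int32)
    n_eval = 0
    for mi in range(masks.shape[0]):
        T = masks[mi]
        szT = _popcnt64(T, tab)
        for ci in range(cols.shape[0]):
            u = cols[ci]
            cub = np.int64(1) << colors[u]
            if T & cub == 0:
                continue
            rem = T & ~cub
            found = False
            best = 0.0
            qp = (rem - 1) & rem
            while True:
                Q = cub | qp
                R = T & ~Q
                if present[Q, u]:
                    AQ = entA[Q, u]
                    szQ = _popcnt64(Q, tab)
                    for ei in range(indptr[u], indptr[u + 1]):
                        v = indices[ei]
                        if not present[R, v]:
                            continue
                        n_eval += 1
                        score = AQ + entA[R, v]
                        take = False
                        if not found or score > best:
                            take = True
                        elif score == best:
                            _merge_sorted(verts[Q, u], szQ,
                                          verts[R, v], szT - szQ, cand_verts)
                            if _lex_less(cand_verts, best_verts, szT):
                                take = True
                        if take:
                            found = True
                            best = score
                            _merge_sorted(verts[Q, u], szQ,
                                          verts[R, v], szT - szQ, best_verts)
                if qp == 0:
                    break
                qp = (qp - 1) & rem
            if found:
                present[T, u] = 1
                entA[T, u] = best
                for i in range(szT):
                    verts[T, u, i] = best_verts[i]
    counter[0] += n_eval


def pack_bits(rows: np.ndarray) -> np.ndarray:
    """Pack binary rows (n, m) into (n, ceil(m/63)) int64 words."""
    rows = np.asarray(rows, dtype=np.uint8)
    n, m = rows.shape
    nw = max(1, -(-m // WORD_BITS))
    out = np.zeros((n, nw), dtype=np.int64)
    for j in range(m):
        w, b = divmod(j, WORD_BITS)
        out[:, w] |= rows[:, j].astype(np.int64) << b
    return out
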