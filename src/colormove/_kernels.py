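"""Numba kernels for the hot loops: Kasai LCP, threshold computation, PML queries.

These are private; the public API in :mod:`text_core`, :mod:`move_index` and
:mod:`classifier` wraps them.  All kernels operate on flat numpy arrays so a
single compiled function serves every index size.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Repositioning strategy codes shared with classifier.py
STRATEGY_TRUE = 0
STRATEGY_ALWAYS_UP = 1
STRATEGY_MID_RUN = 2


@njit(cache=True)
def kasai_lcp(codes, sa):
    """LCP array via Kasai's algorithm.  LCP[0]=0, LCP[i]=lcp(SA[i-1], SA[i])."""
    n = sa.shape[0]
    rank = np.empty(n, np.int64)
    for i in range(n):
        rank[sa[i]] = i
    lcp = np.zeros(n, np.int64)
    h = 0
    for i in range(n):
        if rank[i] > 0:
            j = sa[rank[i] - 1]
            while i + h < n and j + h < n and codes[i + h] == codes[j + h]:
                h += 1
            lcp[rank[i]] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


@njit(cache=True)
def thresholds_for_char(run_starts, run_lens, run_chars, c, occ, lcp, out):
    """Fill ``out`` with the repositioning threshold of character ``c`` per run.

    For a run [s, s+L) whose character differs from ``c``, let ``a`` be the
    nearest BWT offset above the run carrying ``c`` and ``b`` the nearest
    below.  The threshold is the within-run offset of the first (topmost)
    minimum of LCP over (a, b], clamped to [0, L]: offsets strictly below it
    keep a longer match by repositioning up, the rest by going down.  With no
    occurrence above the threshold is 0 (always down); with none below it is
    L (always up).
    """
    r = run_starts.shape[0]
    cached_a = np.int64(-2)
    cached_b = np.int64(-2)
    cached_p = np.int64(-1)
    for ri in range(r):
        if run_chars[ri] == c:
            out[ri] = 0
            continue
        s = run_starts[ri]
        L = run_lens[ri]
        if occ.shape[0] == 0:
            out[ri] = 0
            continue
        idx = np.searchsorted(occ, s)
        if idx == 0:
            out[ri] = 0
        elif idx == occ.shape[0]:
            out[ri] = L
        else:
            a = occ[idx - 1]
            b = occ[idx]
            if a != cached_a or b != cached_b:
                best = lcp[a + 1]
                p = a + 1
                for q in range(a + 2, b + 1):
                    if lcp[q] < best:
                        best = lcp[q]
                        p = q
                cached_a = a
                cached_b = b
                cached_p = p
            t = cached_p - s
            if t < 0:
                t = 0
            if t > L:
                t = L
            out[ri] = t


@njit(cache=True)
def pml_kernel(run_chars, run_lens, dest_run, dest_off, thresh, strategy,
               read, present):
    """Pseudo-matching lengths of ``read`` against a move table.

    ``read`` holds alphabet codes (1..4 for A,C,G,T; anything < 1 is treated
    as a never-matching character).  Returns ``(pml, visited)`` where
    ``visited[k]`` is the run index reached after the LF step at read
    position k, or -1 when the step was skipped (character absent from the
    BWT or non-ACGT).
    """
    r = run_chars.shape[0]
    m = read.shape[0]
    pml = np.zeros(m, np.int32)
    visited = np.full(m, -1, np.int32)
    i = r - 1
    j = run_lens[r - 1] - 1
    ell = 0
    for k in range(m - 1, -1, -1):
        c = read[k]
        if c < 1 or not present[c]:
            ell = 0
            continue
        if c == run_chars[i]:
            ell += 1
        else:
            if strategy == STRATEGY_TRUE:
                th = thresh[i, c - 1]
            elif strategy == STRATEGY_ALWAYS_UP:
                th = run_lens[i]
            else:
                th = (run_lens[i] + 1) // 2
            ni = np.int64(-1)
            if j < th:
                for q in range(i - 1, -1, -1):
                    if run_chars[q] == c:
                        ni = q
                        break
                if ni >= 0:
                    j = run_lens[ni] - 1
                else:  # nothing above: fall back down
                    for q in range(i + 1, r):
                        if run_chars[q] == c:
                            ni = q
                            break
                    j = 0
            else:
                for q in range(i + 1, r):
                    if run_chars[q] == c:
                        ni = q
                        break
                if ni >= 0:
                    j = 0
                else:  # nothing below: fall back up
                    for q in range(i - 1, -1, -1):
                        if run_chars[q] == c:
                            ni = q
                            break
                    j = run_lens[ni] - 1
            i = ni
            ell = 0
        pml[k] = ell
        # LF step with fast-forward across run boundaries
        di = dest_run[i]
        dj = dest_off[i] + j
        while dj >= run_lens[di]:
            dj -= run_lens[di]
            di += 1
        i = di
        j = dj
        visited[k] = i
    return pml, visited
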