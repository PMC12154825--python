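"""Brute-force reference implementations used to validate the index.

Everything here is quadratic-time by design and shares no logic with the
production code paths: suffix/rotation sorting uses Python ``sorted`` on
string slices, matching statistics use substring scans, and LF uses
character counting.  Intended for texts up to a few thousand characters.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Sequence


def brute_bwt(S: str) -> tuple[list[int], str]:
    """(SA, BWT) by sorting the cyclic rotations of ``S``."""
    if not S.endswith("$") or S.count("$") != 1:
        raise ValueError("text must end with a single unique '$'")
    n = len(S)
    order = sorted(range(n), key=lambda i: S[i:] + S[:i])
    bwt = "".join(S[(i - 1) % n] for i in order)
    return order, bwt


def brute_lf(bwt: str) -> list[int]:
    """Rank-based LF mapping: LF(i) = C[bwt[i]] + rank(bwt[i], i)."""
    chars = sorted(set(bwt))
    count = {c: 0 for c in chars}
    for c in bwt:
        count[c] += 1
    first = {}
    total = 0
    for c in chars:
        first[c] = total
        total += count[c]
    seen = {c: 0 for c in chars}
    lf = []
    for c in bwt:
        lf.append(first[c] + seen[c])
        seen[c] += 1
    return lf


def brute_matching_statistics(S: str, R: str) -> list[int]:
    """MS[k] = length of the longest prefix of R[k:] occurring anywhere in S."""
    m = len(R)
    ms = [0] * m
    prev = 0
    for k in range(m - 1, -1, -1):
        # MS[k] <= MS[k+1] + 1, and occurrence is prefix-closed
        length = min(prev + 1, m - k)
        while length > 0 and R[k : k + length] not in S:
            length -= 1
        ms[k] = length
        prev = length
    return ms


@dataclass
class Interval:
    lo: int
    hi: int  # half-open row interval of the BWM

    @property
    def width(self) -> int:
        return self.hi - self.lo


def brute_backward_search(S: str, pattern: str) -> Interval:
    """BWM row interval of rotations prefixed by ``pattern`` (possibly empty)."""
    sa, _ = brute_bwt(S)
    suffixes = [S[i:] for i in sa]
    lo = bisect_left(suffixes, pattern)
    hi = lo
    while hi < len(suffixes) and suffixes[hi].startswith(pattern):
        hi += 1
    return Interval(lo, hi)


def brute_run_colors(
    S: str,
    boundaries: Sequence[tuple[int, int]],
    runs: Sequence[tuple[int, int]],
) -> list[set[int]]:
    """Per-run document sets directly from the sorted suffixes.

    ``runs`` are (start, length) intervals over flat BWT offsets.  The
    terminator suffix belongs to the last document.
    """
    sa, _ = brute_bwt(S)

    def doc_of(pos: int) -> int:
        for d, (s, e) in enumerate(boundaries):
            if s <= pos < e:
                return d
        return len(boundaries) - 1  # terminator -> last document

    colors = []
    for start, length in runs:
        colors.append({doc_of(sa[p]) for p in range(start, start + length)})
    return colors
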