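"""Move table: O(r)-row representation of the BWT supporting LF stepping.

Each BWT run becomes one row storing its character, length, the LF-mapping
destination of the run head as a (run, offset) pair, the repositioning
thresholds, and (once colors are assigned) a color id.  A BWT offset is a
pair (i, j): offset j into run i.  LF of (i, j) is the destination of the
run head shifted by j, "fast-forwarded" across run boundaries.

No run splitting/balancing is performed: at desk scale the fast-forward
loop is short and the constant-time guarantee of the balanced variant is
not needed for correctness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from . import _kernels
from .text_core import ALPHABET, RunSet, SuffixStructures, ThresholdSet, encode

#: Repositioning strategy names -> kernel codes.
STRATEGIES = {
    "true": _kernels.STRATEGY_TRUE,
    "always-up": _kernels.STRATEGY_ALWAYS_UP,
    "mid-run": _kernels.STRATEGY_MID_RUN,
}


class Position(NamedTuple):
    run: int
    offset: int


@dataclass
class MoveTable:
    """Per-run rows of the move structure, in BWT order."""

    n: int
    run_chars: np.ndarray   # uint8 alphabet codes, length r
    run_lens: np.ndarray    # int64
    starts: np.ndarray      # int64 flat BWT start of each run
    dest_run: np.ndarray    # int64 LF destination run of the run head
    dest_off: np.ndarray    # int64 offset within the destination run
    thresholds: Optional[np.ndarray] = None  # (r, 4) int64, or None
    color_ids: Optional[np.ndarray] = None   # int64, filled by color_index
    char_present: np.ndarray = field(
        default_factory=lambda: np.zeros(len(ALPHABET), dtype=np.bool_)
    )

    @property
    def r(self) -> int:
        return len(self.run_chars)

    def run_char(self, i: int) -> str:
        return ALPHABET[self.run_chars[i]]


def build_move_table(
    runs: RunSet,
    structures: SuffixStructures,
    thresholds: ThresholdSet | None = None,
) -> MoveTable:
    """Assemble the move table from the runs; LF of each run head is computed
    by character counting (rank) over the BWT."""
    bwt = structures.bwt_codes
    n = len(bwt)
    # LF(p) = C[bwt[p]] + rank(p); a stable character sort realizes exactly
    # this mapping, so inverting the argsort gives LF for every offset at once
    order = np.argsort(bwt, kind="stable")
    lf_all = np.empty(n, dtype=np.int64)
    lf_all[order] = np.arange(n)
    lf_heads = lf_all[runs.starts]
    dest_run = np.searchsorted(runs.starts, lf_heads, side="right") - 1
    dest_off = lf_heads - runs.starts[dest_run]
    present = np.zeros(len(ALPHABET), dtype=np.bool_)
    present[np.unique(bwt)] = True
    return MoveTable(
        n=n,
        run_chars=runs.chars.astype(np.uint8),
        run_lens=runs.lengths.astype(np.int64),
        starts=runs.starts.astype(np.int64),
        dest_run=dest_run.astype(np.int64),
        dest_off=dest_off.astype(np.int64),
        thresholds=None if thresholds is None else thresholds.thresholds,
        char_present=present,
    )


def lf_step(table: MoveTable, pos: Position) -> Position:
    """One LF step: hop to the run-head destination plus the in-run offset,
    then fast-forward while the offset overruns the destination run."""
    i, j = pos
    di = int(table.dest_run[i])
    dj = int(table.dest_off[i]) + j
    while dj >= table.run_lens[di]:
        dj -= int(table.run_lens[di])
        di += 1
    return Position(di, dj)


def _effective_threshold(table: MoveTable, i: int, c_code: int, strategy: str) -> int:
    code = STRATEGIES[strategy]
    if code == _kernels.STRATEGY_TRUE:
        if table.thresholds is None:
            raise ValueError(
                "index has no thresholds; use the 'mid-run' or 'always-up' "
                "repositioning strategy"
            )
        return int(table.thresholds[i, c_code - 1])
    if code == _kernels.STRATEGY_ALWAYS_UP:
        return int(table.run_lens[i])
    return (int(table.run_lens[i]) + 1) // 2


def reposition(
    table: MoveTable, pos: Position, c: str, strategy: str = "true"
) -> Optional[Position]:
    """Move to the nearest run carrying ``c``, up or down per the strategy.

    Up lands at the last offset of the nearest preceding run of ``c``; down
    at the first offset of the nearest following run.  If the chosen
    direction has no such run the other direction is used; ``None`` when
    ``c`` does not occur in the BWT at all.
    """
    c_code = int(encode(c)[0])
    if c_code < 1 or not table.char_present[c_code]:
        return None
    i, j = pos
    if table.run_chars[i] == c_code:
        raise ValueError("reposition requires a mismatching run character")
    th = _effective_threshold(table, i, c_code, strategy)
    up_first = j < th
    for direction in ((-1, 1) if up_first else (1, -1)):
        rng = range(i - 1, -1, -1) if direction == -1 else range(i + 1, table.r)
        for q in rng:
            if table.run_chars[q] == c_code:
                if direction == -1:
                    return Position(q, int(table.run_lens[q]) - 1)
                return Position(q, 0)
    return None  # unreachable when char_present[c_code]


def to_flat_offset(table: MoveTable, pos: Position) -> int:
    return int(table.starts[pos.run]) + pos.offset


def flat_to_position(table: MoveTable, flat: int) -> Position:
    i = int(np.searchsorted(table.starts, flat, side="right")) - 1
    return Position(i, flat - int(table.starts[i]))
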