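"""Run colors: which documents contribute suffixes to each BWT run.

A run's *color* is the set of document ids of its rows (multiplicities
discarded).  Distinct colors are deduplicated into a color table keyed by a
small integer color id — on repetitive pangenomes the number of distinct
colors |C| is far below the number of runs r, and r/|C| measures the
compression won by storing one id per run instead of one set per run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .move_index import MoveTable
from .text_core import RunSet, SuffixStructures


@dataclass(frozen=True)
class Color:
    """A document subset with dense (bitmask) and sparse encodings."""

    docs: frozenset[int]

    def as_sparse(self) -> tuple[int, ...]:
        return tuple(sorted(self.docs))

    def as_dense(self, n_docs: int) -> int:
        mask = 0
        for d in self.docs:
            if not 0 <= d < n_docs:
                raise ValueError(f"doc id {d} outside 0..{n_docs - 1}")
            mask |= 1 << d
        return mask

    @classmethod
    def from_sparse(cls, ids: Sequence[int]) -> "Color":
        return cls(frozenset(int(i) for i in ids))

    @classmethod
    def from_dense(cls, mask: int) -> "Color":
        docs = set()
        d = 0
        while mask:
            if mask & 1:
                docs.add(d)
            mask >>= 1
            d += 1
        return cls(frozenset(docs))


def compute_run_colors(runs: RunSet, structures: SuffixStructures) -> list[frozenset[int]]:
    """Per run, the set of documents of its rows (from the document array)."""
    r = runs.r
    run_of_pos = np.repeat(np.arange(r, dtype=np.int64), runs.lengths)
    pairs = np.stack([run_of_pos, structures.DA.astype(np.int64)], axis=1)
    uniq = np.unique(pairs, axis=0)
    split = np.searchsorted(uniq[:, 0], np.arange(1, r))
    return [frozenset(chunk.tolist()) for chunk in np.split(uniq[:, 1], split)]


@dataclass
class ColorTable:
    """Deduplicated colors plus the per-run color id assignment."""

    colors: list[Color]
    run_color_ids: np.ndarray  # int64, length r
    n_docs: int
    representation: str = "dense"  # informational: dense bitvector vs sparse list

    @property
    def num_colors(self) -> int:
        return len(self.colors)

    def docs_of_run(self, run_index: int) -> frozenset[int]:
        return self.colors[int(self.run_color_ids[run_index])].docs


def build_color_table(
    run_colors: Sequence[frozenset[int]],
    n_docs: int,
    representation: str | None = None,
) -> ColorTable:
    """Number distinct colors by first appearance in run order (deterministic)
    and map every run to its color id.

    The default representation is dense (|D|-bit vectors) for up to 64
    documents and sparse (sorted id lists) beyond; both decode identically,
    the choice only affects the reported size accounting.
    """
    if not run_colors:
        raise ValueError("no run colors")
    if representation is None:
        representation = "dense" if n_docs <= 64 else "sparse"
    seen: dict[frozenset[int], int] = {}
    colors: list[Color] = []
    ids = np.empty(len(run_colors), dtype=np.int64)
    for i, cset in enumerate(run_colors):
        if not cset:
            raise ValueError(f"run {i} has an empty color")
        cid = seen.get(cset)
        if cid is None:
            cid = len(colors)
            seen[cset] = cid
            colors.append(Color(frozenset(cset)))
        ids[i] = cid
    return ColorTable(
        colors=colors, run_color_ids=ids, n_docs=n_docs,
        representation=representation,
    )


def assign_colors(table: MoveTable, color_table: ColorTable) -> None:
    """Fill the move rows' color-id column in place."""
    if len(color_table.run_color_ids) != table.r:
        raise ValueError("color table does not match the move table run count")
    table.color_ids = color_table.run_color_ids


@dataclass
class ColorStats:
    r: int
    num_colors: int
    ratio: float            # r / |C|
    mean_set_bits: float    # b: average number of documents per color
    n_docs: int
    dense_bits: int         # |C| x |D|
    sparse_integers: int    # |C| x b (total set bits)
    frequency: np.ndarray   # runs per color id, descending
    top_k_coverage: np.ndarray  # cumulative fraction of runs, top-K colors

    def as_dict(self) -> dict:
        return {
            "r": self.r,
            "num_colors": self.num_colors,
            "ratio": self.ratio,
            "mean_set_bits": self.mean_set_bits,
            "n_docs": self.n_docs,
            "dense_bits": self.dense_bits,
            "sparse_integers": self.sparse_integers,
        }


def color_stats(table: ColorTable, top_k: int = 10) -> ColorStats:
    sizes = np.array([len(c.docs) for c in table.colors], dtype=np.int64)
    counts = np.bincount(table.run_color_ids, minlength=table.num_colors)
    freq = np.sort(counts)[::-1]
    r = int(len(table.run_color_ids))
    k = min(top_k, len(freq))
    coverage = np.cumsum(freq[:k]) / r
    b = float(sizes.mean())
    return ColorStats(
        r=r,
        num_colors=table.num_colors,
        ratio=r / table.num_colors,
        mean_set_bits=b,
        n_docs=table.n_docs,
        dense_bits=table.num_colors * table.n_docs,
        sparse_integers=int(sizes.sum()),
        frequency=freq,
        top_k_coverage=coverage,
    )
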