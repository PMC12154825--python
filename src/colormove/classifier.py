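"""PML queries, color-tally scoring, the binary average-PML gate, and
multi-class / LCA classification.

The pseudo-matching length (PML) of a read position is a cheap lower bound
on its matching statistic, computed by tracking a single BWT offset right to
left: a match extends the current length, a mismatch repositions to a nearby
run of the required character and resets it.  Multi-class scores tally, for
every position with a positive PML, the documents in the color of the run
reached after the LF step.  A read first passes a binary gate — its average
PML must exceed a cutoff calibrated as the 95th percentile of null-read
averages (a level-0.05 test) — before the highest-scoring document (and up
to ``max_secondary`` runners-up within a score ratio) determine its taxon,
resolving multiple reports to their LCA.

References are indexed forward-only; each read is queried in both
orientations and the orientation with the higher average PML is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from ._kernels import pml_kernel
from .color_index import ColorTable
from .move_index import STRATEGIES, MoveTable
from .taxonomy import TaxonomyTree, lca
from .text_core import encode, reverse_complement


@dataclass
class PMLResult:
    """PMLs plus, per position, the post-LF run index (-1 for skipped steps)."""

    pml: np.ndarray
    visited: np.ndarray
    orientation: str = "+"

    @property
    def m(self) -> int:
        return len(self.pml)


def compute_pmls(table: MoveTable, read: str, strategy: str = "true") -> PMLResult:
    """Run the PML algorithm over ``read`` (right to left).

    The tracked offset starts at the last BWT offset.  Read characters
    outside ACGT, or absent from the BWT, contribute PML 0 and skip the LF
    step, leaving the tracked position unchanged.
    """
    if not read:
        raise ValueError("empty read")
    code = STRATEGIES[strategy]
    if code == STRATEGIES["true"] and table.thresholds is None:
        raise ValueError(
            "index has no thresholds; use the 'mid-run' or 'always-up' strategy"
        )
    thresh = table.thresholds
    if thresh is None:
        thresh = np.zeros((table.r, 4), dtype=np.int64)
    read_codes = encode(read.upper())
    pml, visited = pml_kernel(
        table.run_chars, table.run_lens, table.dest_run, table.dest_off,
        thresh, code, read_codes, table.char_present,
    )
    return PMLResult(pml=pml, visited=visited)


def average_pml(result: PMLResult) -> float:
    return float(result.pml.sum()) / result.m


def compute_pmls_best_orientation(
    table: MoveTable, read: str, strategy: str = "true"
) -> PMLResult:
    """Query both strands, keep the one with the higher average PML
    (forward wins ties)."""
    fwd = compute_pmls(table, read, strategy)
    rev = compute_pmls(table, reverse_complement(read.upper()), strategy)
    if average_pml(rev) > average_pml(fwd):
        rev.orientation = "-"
        return rev
    return fwd


def score_read(result: PMLResult, colors: ColorTable) -> dict[int, int]:
    """Tally document scores: each position with PML > 0 adds 1 to every
    document in the color of the run it visited."""
    mask = (result.pml > 0) & (result.visited >= 0)
    scores: dict[int, int] = {}
    if not mask.any():
        return scores
    runs, counts = np.unique(result.visited[mask], return_counts=True)
    for run, cnt in zip(runs, counts):
        for d in colors.docs_of_run(int(run)):
            scores[d] = scores.get(d, 0) + int(cnt)
    return scores


@dataclass
class BinaryCalibration:
    """Average-PML cutoff for the in-index gate."""

    cutoff: float
    percentile: float
    n_null: int


def calibrate_cutoff(
    null_avg_pmls: Sequence[float], percentile: float = 95.0
) -> BinaryCalibration:
    """Nearest-rank percentile of the null-read average PMLs.

    Deterministic and well defined for small n: the cutoff is the
    ceil(p/100 * n)-th smallest value.
    """
    vals = sorted(float(v) for v in null_avg_pmls)
    n = len(vals)
    if n < 20:
        raise ValueError(f"need at least 20 null reads to calibrate, got {n}")
    rank = max(1, math.ceil(percentile / 100.0 * n))
    return BinaryCalibration(
        cutoff=vals[min(rank, n) - 1], percentile=percentile, n_null=n
    )


@dataclass
class ReadClassification:
    read_id: str
    status: str                       # "classified" | "unclassified"
    avg_pml: float
    reported_docs: list[int] = field(default_factory=list)  # ordered by score
    scores: dict[int, int] = field(default_factory=dict)    # of reported docs
    assigned_taxon: Optional[int] = None
    orientation: str = "+"
    read_length: int = 0

    @property
    def classified(self) -> bool:
        return self.status == "classified"


def classify_read(
    scores: Mapping[int, int],
    avg_pml: float,
    calibration: Optional[BinaryCalibration],
    tree: Optional[TaxonomyTree],
    doc_taxon: Mapping[int, int],
    ratio: float = 0.95,
    max_secondary: int = 1,
    read_id: str = "",
) -> ReadClassification:
    """Gate on average PML, then report Dbest plus close runners-up.

    A read whose average PML is at or below the cutoff is unclassified
    (pass ``calibration=None`` to disable the gate).  Otherwise the document
    with the highest score wins (ties to the smallest doc id); up to
    ``max_secondary`` further documents scoring at least ``ratio`` times the
    best are co-reported, and the assigned taxon is Dbest's taxon when alone,
    else the LCA of all reported documents' taxa.
    """
    if calibration is not None and avg_pml <= calibration.cutoff:
        return ReadClassification(read_id, "unclassified", avg_pml)
    if not scores or max(scores.values()) <= 0:
        return ReadClassification(read_id, "unclassified", avg_pml)
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    best_doc, best_score = ranked[0]
    reported = [best_doc]
    for doc, sc in ranked[1:]:
        if len(reported) - 1 >= max_secondary:
            break
        if sc >= ratio * best_score:
            reported.append(doc)
    taxa = [doc_taxon[d] for d in reported]
    if len(set(taxa)) == 1:
        assigned = taxa[0]
    else:
        if tree is None:
            raise ValueError("multiple reported documents require a taxonomy")
        assigned = lca(tree, taxa)
    return ReadClassification(
        read_id, "classified", avg_pml,
        reported_docs=reported,
        scores={d: scores[d] for d in reported},
        assigned_taxon=assigned,
    )


def classify_reads(
    table: MoveTable,
    colors: ColorTable,
    tree: Optional[TaxonomyTree],
    doc_taxon: Mapping[int, int],
    reads: Sequence[tuple[str, str]],
    strategy: str = "true",
    calibration: Optional[BinaryCalibration] = None,
    ratio: float = 0.95,
    max_secondary: int = 1,
) -> list[ReadClassification]:
    """Classify (read_id, sequence) pairs end to end."""
    out = []
    for read_id, seq in reads:
        res = compute_pmls_best_orientation(table, seq, strategy)
        avg = average_pml(res)
        if calibration is not None and avg <= calibration.cutoff:
            cls = ReadClassification(read_id, "unclassified", avg)
        else:
            scores = score_read(res, colors)
            cls = classify_read(
                scores, avg, None, tree, doc_taxon,
                ratio=ratio, max_secondary=max_secondary, read_id=read_id,
            )
        cls.orientation = res.orientation
        cls.read_length = len(seq)
        out.append(cls)
    return out


def average_pmls(
    table: MoveTable, reads: Sequence[tuple[str, str]], strategy: str = "true"
) -> np.ndarray:
    """Best-orientation average PML per read (the binary-gate statistic)."""
    return np.array(
        [
            average_pml(compute_pmls_best_orientation(table, seq, strategy))
            for _, seq in reads
        ]
    )
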