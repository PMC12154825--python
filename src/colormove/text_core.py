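"""Concatenated reference text and its suffix-based structures.

A multi-document reference (genomes grouped into classification units called
*documents*) is concatenated into a single string ``S`` terminated by one
``$`` that is lexicographically smallest.  From ``S`` we derive the suffix
array, BWT, LCP array and document array, the maximal equal-letter BWT runs,
and the per-run repositioning thresholds.  Everything downstream — the move
table, the run colors, PML queries — is built from these structures.

Coordinates are 0-based; intervals are half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._kernels import kasai_lcp, thresholds_for_char

logger = logging.getLogger(__name__)

#: Alphabet with the terminator smallest: $ < A < C < G < T.
ALPHABET = "$ACGT"
TERMINATOR = "$"

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _ch in enumerate(ALPHABET):
    _CODE[ord(_ch)] = _i

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_NON_ACGT = re.compile(r"[^ACGT]+")


def encode(seq: str) -> np.ndarray:
    """Map a string over ``$ACGT`` to int8 codes (unknown characters -> -1)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sanitize_sequence(seq: str) -> list[str]:
    """Uppercase and split on maximal non-ACGT stretches.

    Ambiguity codes (N etc.) are removed by splitting the sequence into the
    flanking ACGT pieces, which stay in the same document; no artificial
    adjacency is ever scored because downstream matching is exact.
    """
    pieces = [p for p in _NON_ACGT.split(seq.upper()) if p]
    return pieces


@dataclass
class Document:
    doc_id: int
    name: str
    sequences: list[str]


@dataclass
class DocumentCollection:
    """Ordered documents (the classification units) plus their taxon links."""

    documents: list[Document]
    doc_taxon: dict[int, int] = field(default_factory=dict)

    def validate(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if not ids:
            raise ValueError("empty document collection")
        if ids != list(range(len(ids))):
            raise ValueError("doc_ids must be contiguous 0..|D|-1 in order")
        for d in self.documents:
            for s in d.sequences:
                if not s:
                    raise ValueError(f"document {d.doc_id} has an empty sequence")

    @property
    def n_documents(self) -> int:
        return len(self.documents)


@dataclass
class ConcatText:
    """The documents concatenated in doc_id order, with a single terminator."""

    S: str
    boundaries: list[tuple[int, int]]

    @property
    def n(self) -> int:
        return len(self.S)

    @property
    def terminator_pos(self) -> int:
        return self.n - 1


def build_concat(collection: DocumentCollection, sanitize: bool = True) -> ConcatText:
    """Concatenate all documents and append the unique terminator.

    The terminator is attributed to the last document so that every BWT run
    carries a nonempty color.  With ``sanitize`` (default), non-ACGT stretches
    split sequences into pieces of the same document.
    """
    collection.validate()
    parts: list[str] = []
    boundaries: list[tuple[int, int]] = []
    pos = 0
    for doc in collection.documents:
        start = pos
        for seq in doc.sequences:
            pieces = sanitize_sequence(seq) if sanitize else [seq.upper()]
            if sanitize and len(pieces) != 1:
                logger.info(
                    "document %d: sequence split into %d ACGT pieces during "
                    "sanitization", doc.doc_id, len(pieces),
                )
            for p in pieces:
                if _NON_ACGT.search(p):
                    raise ValueError(
                        f"document {doc.doc_id}: illegal characters remain"
                    )
                parts.append(p)
                pos += len(p)
        if pos == start:
            raise ValueError(f"document {doc.doc_id} is empty after sanitization")
        boundaries.append((start, pos))
    parts.append(TERMINATOR)
    return ConcatText(S="".join(parts), boundaries=boundaries)


def suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (Manber–Myers) with numpy lexsort.

    O(n log^2 n); comfortably handles the megabase-scale concatenations used
    at desk scale.
    """
    n = len(codes)
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = codes.astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        new_rank = np.empty(n, dtype=np.int64)
        bump = (rank[sa[1:]] != rank[sa[:-1]]) | (key2[sa[1:]] != key2[sa[:-1]])
        new_rank[sa[0]] = 0
        new_rank[sa[1:]] = np.cumsum(bump)
        rank = new_rank
        if rank[sa[-1]] == n - 1:
            return sa.astype(np.int64)
        k *= 2


@dataclass
class SuffixStructures:
    """SA/BWT/LCP/document-array bundle for a concatenated text."""

    text: ConcatText
    SA: np.ndarray
    bwt_codes: np.ndarray
    LCP: np.ndarray
    DA: np.ndarray

    @property
    def BWT(self) -> str:
        return decode(self.bwt_codes)

    @property
    def n(self) -> int:
        return len(self.SA)


def build_suffix_structures(text: ConcatText) -> SuffixStructures:
    S = text.S
    n = len(S)
    if n < 2 or S[-1] != TERMINATOR or TERMINATOR in S[:-1]:
        raise ValueError("text must end with a single unique terminator")
    codes = encode(S)
    if (codes < 0).any():
        raise ValueError("text contains characters outside $ACGT")
    sa = suffix_array(codes)
    bwt = codes[(sa - 1) % n]
    lcp = kasai_lcp(codes, sa)
    doc_starts = np.array([b[0] for b in text.boundaries], dtype=np.int64)
    # terminator position falls past the last start, so it lands in the last
    # document, as intended
    da = (np.searchsorted(doc_starts, sa, side="right") - 1).astype(np.int32)
    return SuffixStructures(text=text, SA=sa, bwt_codes=bwt, LCP=lcp, DA=da)


def inverse_bwt(bwt: str) -> str:
    """Reconstruct the text from its BWT by walking the LF mapping."""
    codes = encode(bwt)
    n = len(codes)
    counts = np.bincount(codes, minlength=len(ALPHABET))
    first = np.concatenate(([0], np.cumsum(counts)[:-1]))
    order = np.argsort(codes, kind="stable")
    # LF[i] = first[c] + rank_c(i); stable argsort inverts exactly that
    lf = np.empty(n, dtype=np.int64)
    lf[order] = np.arange(n)
    # row 0 is the rotation starting with '$'; its BWT char is the text's
    # last proper character, and LF walks the text right to left
    out = []
    i = 0
    for _ in range(n):
        out.append(bwt[i])
        i = int(lf[i])
    s = "".join(reversed(out))
    return s[1:] + s[0]  # rotate the leading terminator to the end


@dataclass
class RunSet:
    """Maximal equal-letter runs of the BWT."""

    starts: np.ndarray
    chars: np.ndarray  # alphabet codes
    lengths: np.ndarray

    @property
    def r(self) -> int:
        return len(self.starts)

    def char_str(self, i: int) -> str:
        return ALPHABET[self.chars[i]]


def find_runs(bwt_codes: np.ndarray | str) -> RunSet:
    if isinstance(bwt_codes, str):
        bwt_codes = encode(bwt_codes)
    n = len(bwt_codes)
    if n == 0:
        raise ValueError("empty BWT")
    breaks = np.flatnonzero(bwt_codes[1:] != bwt_codes[:-1]) + 1
    starts = np.concatenate(([0], breaks)).astype(np.int64)
    ends = np.concatenate((breaks, [n]))
    return RunSet(
        starts=starts,
        chars=bwt_codes[starts].astype(np.uint8),
        lengths=(ends - starts).astype(np.int64),
    )


@dataclass
class ThresholdSet:
    """Per run, per query character (A,C,G,T), the up/down repositioning cut.

    Within-run offsets ``j < thresholds[run, code-1]`` reposition up, the
    rest down.  Equals the run length when the character is absent below the
    run, 0 when absent above.
    """

    thresholds: np.ndarray  # shape (r, 4), int64


def compute_thresholds(runs: RunSet, structures: SuffixStructures) -> ThresholdSet:
    r = runs.r
    out = np.zeros((r, 4), dtype=np.int64)
    bwt = structures.bwt_codes
    lcp = structures.LCP
    for c in range(1, 5):  # A,C,G,T
        occ = np.flatnonzero(bwt == c).astype(np.int64)
        thresholds_for_char(
            runs.starts, runs.lengths, runs.chars, np.uint8(c), occ, lcp,
            out[:, c - 1],
        )
    return ThresholdSet(thresholds=out)


def shared_lcp(run_index: int, runs: RunSet, structures: SuffixStructures) -> int:
    """Longest prefix shared by every row of a run.

    For a length-1 run this is the suffix length (vacuous minimum).
    """
    s = int(runs.starts[run_index])
    L = int(runs.lengths[run_index])
    if L == 1:
        return structures.n - int(structures.SA[s])
    return int(structures.LCP[s + 1 : s + L].min())
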