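"""File I/O, the end-to-end index build, and index serialization.

External formats: FASTA/FASTQ (plain or gzip) for sequences; TSVs for the
sequence-to-document map (``sequence_id <TAB> doc_id``), document-to-taxon
map (``doc_id <TAB> taxon_id``), read truth (``read_id <TAB> taxon_id`` with
``-`` for reads absent from the index), and the taxonomy (see
:mod:`colormove.taxonomy`).  A built index is persisted as a single
compressed numpy container with a JSON header.
"""

from __future__ import annotations

import gzip
import json
import logging
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .classifier import ReadClassification
from .color_index import (Color, ColorTable, assign_colors, build_color_table,
                          color_stats, compute_run_colors)
from .move_index import MoveTable, build_move_table
from .simdata import SimRead
from .taxonomy import TaxonomyTree, build_taxonomy
from .text_core import (Document, DocumentCollection, build_concat,
                        build_suffix_structures, compute_thresholds, find_runs)

logger = logging.getLogger(__name__)

INDEX_FORMAT_VERSION = 1


class IndexFormatError(ValueError):
    """Raised for corrupt or version-incompatible index files."""


@dataclass
class SeqEntry:
    id: str
    sequence: str
    qualities: Optional[str] = None


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(path) -> str:
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    ext = Path(name).suffix.lower()
    if ext in {".fq", ".fastq"}:
        return "fastq"
    if ext in {".fa", ".fasta", ".fna", ".ffn"}:
        return "fasta"
    raise ValueError(f"cannot infer sequence format from {path!r}")


def read_sequences(path) -> list[SeqEntry]:
    """Read FASTA/FASTQ (optionally gzipped) into upper-cased records."""
    fmt = _sniff_format(path)
    entries: list[SeqEntry] = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            qual = None
            if fmt == "fastq":
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            entries.append(SeqEntry(rec.id, str(rec.seq).upper(), qual))
    if not entries:
        raise ValueError(f"{path}: no sequence records found")
    return entries


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(path, records: Iterable[tuple[str, str]]) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_reads_fastq(path, reads: Sequence[SimRead]) -> None:
    write_fastq(path, ((r.read_id, r.sequence) for r in reads))


def write_truth(path, reads: Sequence[SimRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            label = "-" if r.taxon_id is None else str(r.taxon_id)
            fh.write(f"{r.read_id}\t{label}\n")


def read_truth(path) -> dict[str, object]:
    df = pd.read_csv(path, sep="\t", header=None, names=["read_id", "taxon"],
                     dtype=str)
    return {
        row.read_id: ("-" if row.taxon == "-" else int(row.taxon))
        for row in df.itertuples()
    }


def write_doc_map(path, collection: DocumentCollection,
                  seq_names: dict[int, list[str]]) -> None:
    with open(path, "w") as fh:
        for doc in collection.documents:
            for name in seq_names[doc.doc_id]:
                fh.write(f"{name}\t{doc.doc_id}\n")


def write_doc_taxon(path, doc_taxon: dict[int, int]) -> None:
    with open(path, "w") as fh:
        for d, t in sorted(doc_taxon.items()):
            fh.write(f"{d}\t{t}\n")


def write_taxonomy(path, tree: TaxonomyTree) -> None:
    with open(path, "w") as fh:
        for nid in sorted(tree.nodes):
            parent, rank, name = tree.nodes[nid]
            fh.write(f"{nid}\t{parent}\t{rank}\t{name}\n")


def collection_from_files(ref_fasta, docmap_tsv, doc_taxon_tsv=None) -> DocumentCollection:
    """Assemble a document collection from a multi-FASTA and its maps.

    Every FASTA record must be mapped to a document; doc ids must be the
    contiguous integers 0..|D|-1.
    """
    entries = read_sequences(ref_fasta)
    dm = pd.read_csv(docmap_tsv, sep="\t", header=None,
                     names=["seq_id", "doc_id"], dtype={"seq_id": str})
    seq_doc = dict(zip(dm.seq_id, dm.doc_id.astype(int)))
    unmapped = [e.id for e in entries if e.id not in seq_doc]
    if unmapped:
        raise ValueError(f"sequences missing from the document map: {unmapped[:5]}")
    by_doc: dict[int, list[str]] = {}
    for e in entries:
        by_doc.setdefault(seq_doc[e.id], []).append(e.sequence)
    doc_ids = sorted(by_doc)
    if doc_ids != list(range(len(doc_ids))):
        raise ValueError("doc ids in the map must be contiguous 0..|D|-1")
    doc_taxon: dict[int, int] = {}
    if doc_taxon_tsv is not None:
        dt = pd.read_csv(doc_taxon_tsv, sep="\t", header=None,
                         names=["doc_id", "taxon_id"])
        doc_taxon = dict(zip(dt.doc_id.astype(int), dt.taxon_id.astype(int)))
    docs = [Document(d, f"doc_{d}", by_doc[d]) for d in doc_ids]
    return DocumentCollection(documents=docs, doc_taxon=doc_taxon)


@dataclass
class IndexBundle:
    """Everything needed to classify reads: move table, colors, documents,
    taxon links and (optionally) the taxonomy tree."""

    table: MoveTable
    colors: ColorTable
    doc_names: list[str]
    doc_taxon: dict[int, int]
    taxonomy: Optional[TaxonomyTree] = None

    @property
    def n_docs(self) -> int:
        return len(self.doc_names)

    def stats(self):
        return color_stats(self.colors)


def build_index(
    collection: DocumentCollection,
    taxonomy: Optional[TaxonomyTree] = None,
    with_thresholds: bool = True,
) -> IndexBundle:
    """Full build: concatenate, sort suffixes, find runs, compute thresholds
    (optional), assemble the move table and attach run colors."""
    text = build_concat(collection)
    structures = build_suffix_structures(text)
    runs = find_runs(structures.bwt_codes)
    thresholds = compute_thresholds(runs, structures) if with_thresholds else None
    table = build_move_table(runs, structures, thresholds)
    run_colors = compute_run_colors(runs, structures)
    colors = build_color_table(run_colors, n_docs=collection.n_documents)
    assign_colors(table, colors)
    logger.info(
        "built index: n=%d r=%d |C|=%d |D|=%d thresholds=%s",
        table.n, table.r, colors.num_colors, collection.n_documents,
        with_thresholds,
    )
    return IndexBundle(
        table=table,
        colors=colors,
        doc_names=[d.name for d in collection.documents],
        doc_taxon=dict(collection.doc_taxon),
        taxonomy=taxonomy,
    )


def save_index(bundle: IndexBundle, path) -> None:
    t = bundle.table
    sizes = np.array([len(c.docs) for c in bundle.colors.colors], dtype=np.int64)
    color_offsets = np.concatenate(([0], np.cumsum(sizes)))
    color_docs = np.concatenate(
        [np.array(c.as_sparse(), dtype=np.int64) for c in bundle.colors.colors]
    ) if len(sizes) else np.zeros(0, dtype=np.int64)
    meta = {
        "format_version": INDEX_FORMAT_VERSION,
        "n": t.n,
        "r": t.r,
        "num_colors": bundle.colors.num_colors,
        "n_docs": bundle.n_docs,
        "alphabet": "$ACGT",
        "has_thresholds": t.thresholds is not None,
        "representation": bundle.colors.representation,
        "doc_names": bundle.doc_names,
        "doc_taxon": {str(k): v for k, v in bundle.doc_taxon.items()},
        "taxonomy": None if bundle.taxonomy is None else [
            [nid, *bundle.taxonomy.nodes[nid]] for nid in sorted(bundle.taxonomy.nodes)
        ],
    }
    arrays = {
        "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        "run_chars": t.run_chars,
        "run_lens": t.run_lens,
        "starts": t.starts,
        "dest_run": t.dest_run,
        "dest_off": t.dest_off,
        "color_ids": t.color_ids,
        "char_present": t.char_present,
        "color_offsets": color_offsets,
        "color_docs": color_docs,
    }
    if t.thresholds is not None:
        arrays["thresholds"] = t.thresholds
    np.savez_compressed(path, **arrays)


def load_index(path) -> IndexBundle:
    try:
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
    except (zipfile.BadZipFile, OSError, ValueError, EOFError) as exc:
        raise IndexFormatError(f"{path}: not a readable index file ({exc})") from exc
    try:
        meta = json.loads(bytes(arrays["meta"]).decode())
    except (KeyError, json.JSONDecodeError) as exc:
        raise IndexFormatError(f"{path}: corrupt index header") from exc
    if meta.get("format_version") != INDEX_FORMAT_VERSION:
        raise IndexFormatError(
            f"{path}: index format version {meta.get('format_version')} "
            f"is not supported (expected {INDEX_FORMAT_VERSION})"
        )
    required = {"run_chars", "run_lens", "starts", "dest_run", "dest_off",
                "color_ids", "char_present", "color_offsets", "color_docs"}
    missing = required - set(arrays)
    if missing:
        raise IndexFormatError(f"{path}: missing index arrays {sorted(missing)}")
    table = MoveTable(
        n=int(meta["n"]),
        run_chars=arrays["run_chars"],
        run_lens=arrays["run_lens"],
        starts=arrays["starts"],
        dest_run=arrays["dest_run"],
        dest_off=arrays["dest_off"],
        thresholds=arrays.get("thresholds"),
        color_ids=arrays["color_ids"],
        char_present=arrays["char_present"],
    )
    offs = arrays["color_offsets"]
    docs = arrays["color_docs"]
    colors = [
        Color.from_sparse(docs[offs[i] : offs[i + 1]])
        for i in range(len(offs) - 1)
    ]
    color_table = ColorTable(
        colors=colors,
        run_color_ids=arrays["color_ids"],
        n_docs=int(meta["n_docs"]),
        representation=meta["representation"],
    )
    taxonomy = None
    if meta["taxonomy"] is not None:
        taxonomy = build_taxonomy(
            [(nid, parent, rank, name) for nid, parent, rank, name in meta["taxonomy"]]
        )
    return IndexBundle(
        table=table,
        colors=color_table,
        doc_names=list(meta["doc_names"]),
        doc_taxon={int(k): int(v) for k, v in meta["doc_taxon"].items()},
        taxonomy=taxonomy,
    )


def write_classifications(path, results: Sequence[ReadClassification],
                          taxonomy: Optional[TaxonomyTree] = None) -> None:
    """Per-read output TSV."""
    rows = []
    for c in results:
        rank = ""
        if c.assigned_taxon is not None and taxonomy is not None:
            rank = taxonomy.rank(c.assigned_taxon)
        rows.append({
            "read_id": c.read_id,
            "status": "C" if c.classified else "U",
            "assigned_taxon_id": "" if c.assigned_taxon is None else c.assigned_taxon,
            "assigned_rank": rank,
            "reported_docs": ",".join(map(str, c.reported_docs)),
            "scores": ",".join(str(c.scores[d]) for d in c.reported_docs),
            "avg_pml": f"{c.avg_pml:.4f}",
            "read_length": c.read_length,
            "orientation": c.orientation,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_classifications(path) -> dict[str, Optional[int]]:
    """Read the per-read TSV back as read_id -> assigned taxon (None = U)."""
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str})
    out: dict[str, Optional[int]] = {}
    for row in df.itertuples():
        if row.status == "C":
            out[row.read_id] = int(row.assigned_taxon_id)
        else:
            out[row.read_id] = None
    return out
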