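"""Synthetic pangenomes, taxonomies and noisy long reads with ground truth.

The generator emulates a multi-species bacterial pangenome: one random root
genome, species ancestors derived by substitution at an inter-species rate,
several genomes per species at an intra-species rate, one genome per
species held out for read simulation (the index sees the rest).  Reads are
ONT-like noisy long fragments — truncated-normal lengths, independent
substitution / insertion / deletion errors, half reverse-complemented —
with ground-truth document and taxon labels.  Null reads come from a clade
diverged far beyond the indexed species so that no document in the index
contains them.

Divergence between genomes is substitution-only (no structural variants);
read errors do include indels.  Everything is reproducible from the
parameter seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .taxonomy import TaxonomyTree, build_taxonomy
from .text_core import Document, DocumentCollection

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G on 0..3 codes


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _from_str(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    codes = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate``, uniformly among the
    three other bases."""
    out = codes.copy()
    mask = rng.random(len(codes)) < rate
    k = int(mask.sum())
    if k:
        out[mask] = (out[mask] + rng.integers(1, 4, size=k)) % 4
    return out


@dataclass
class PangenomeSimParams:
    """Study conditions for the synthetic pangenome.

    Defaults emulate a small multi-species bacterial collection: 5 species
    of 3 genomes each (one held out per species), 100 kb genomes, 10%
    inter-species and 1% intra-species substitution divergence.
    """

    n_species: int = 5
    genomes_per_species: int = 3
    genome_length: int = 100_000
    inter_species_divergence: float = 0.10
    intra_species_divergence: float = 0.01
    species_per_genus: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length < 100:
            raise ValueError("genome_length must be >= 100")
        for rate in (self.inter_species_divergence, self.intra_species_divergence):
            if not 0 <= rate < 1:
                raise ValueError("divergences must be in [0, 1)")
        if self.genomes_per_species < 2:
            raise ValueError("need >= 2 genomes per species (one is held out)")


@dataclass
class ReadSimParams:
    """ONT-like read simulation: 9 kb mean length and a 7% total error rate
    (3% substitution, 2% insertion, 2% deletion) by default."""

    n_reads: int = 2000
    length_mean: float = 9000.0
    length_sd: float = 3000.0
    min_length: int = 100
    sub_rate: float = 0.03
    ins_rate: float = 0.02
    del_rate: float = 0.02
    rc_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        rates = (self.sub_rate, self.ins_rate, self.del_rate)
        if any(r < 0 for r in rates) or sum(rates) >= 0.5:
            raise ValueError("error rates must be >= 0 and sum below 0.5")


@dataclass
class ReadSource:
    doc_id: Optional[int]
    taxon_id: Optional[int]
    sequence: str


@dataclass
class SimRead:
    read_id: str
    sequence: str
    doc_id: Optional[int]      # None for null reads
    taxon_id: Optional[int]    # None for null reads
    orientation: str = "+"


def _root_genome(params: PangenomeSimParams) -> np.ndarray:
    rng = np.random.default_rng([params.seed, 0])
    return rng.integers(0, 4, size=params.genome_length, dtype=np.uint8)


def simulate_pangenome(
    params: PangenomeSimParams,
) -> tuple[DocumentCollection, TaxonomyTree, dict[int, str]]:
    """Generate the collection (one document per species), its taxonomy and
    the held-out genome of each species.

    The taxonomy is root -> genus groups (consecutive species share a genus)
    -> species; documents are defined at the species level, so the held-out
    genome's true document is the species it came from.
    """
    params.validate()
    root = _root_genome(params)
    rng = np.random.default_rng([params.seed, 1])
    n_genera = -(-params.n_species // params.species_per_genus)
    rows = [(1, 1, "domain", "sim_root")]
    for g in range(n_genera):
        rows.append((10 + g, 1, "genus", f"genus_{g}"))
    documents: list[Document] = []
    doc_taxon: dict[int, int] = {}
    held_out: dict[int, str] = {}
    for s in range(params.n_species):
        genus = s // params.species_per_genus
        taxon = 100 + s
        rows.append((taxon, 10 + genus, "species", f"species_{s}"))
        ancestor = _mutate(root, params.inter_species_divergence, rng)
        genomes = [
            _mutate(ancestor, params.intra_species_divergence, rng)
            for _ in range(params.genomes_per_species)
        ]
        held_idx = int(rng.integers(params.genomes_per_species))
        held_out[s] = _to_str(genomes[held_idx])
        kept = [g for i, g in enumerate(genomes) if i != held_idx]
        documents.append(
            Document(doc_id=s, name=f"species_{s}", sequences=[_to_str(g) for g in kept])
        )
        doc_taxon[s] = taxon
    collection = DocumentCollection(documents=documents, doc_taxon=doc_taxon)
    tree = build_taxonomy(rows)
    return collection, tree, held_out


def _apply_errors(frag: np.ndarray, params: ReadSimParams,
                  rng: np.random.Generator) -> np.ndarray:
    # substitutions first (always to a different base), then deletions, then
    # single-base insertions before surviving positions
    frag = _mutate(frag, params.sub_rate, rng)
    if params.del_rate > 0:
        frag = frag[rng.random(len(frag)) >= params.del_rate]
    if params.ins_rate > 0 and len(frag):
        ins = rng.random(len(frag)) < params.ins_rate
        counts = 1 + ins.astype(np.int64)
        out = frag[np.repeat(np.arange(len(frag)), counts)]
        slots = np.cumsum(counts) - counts  # first emitted slot per position
        n_ins = int(ins.sum())
        out[slots[ins]] = rng.integers(0, 4, size=n_ins, dtype=np.uint8)
        frag = out
    return frag


def simulate_reads(
    sources: Sequence[ReadSource],
    params: ReadSimParams,
    read_prefix: str = "read",
) -> list[SimRead]:
    """Simulate reads from the given source genomes with ground truth.

    Start positions are uniform, lengths truncated-normal (resampled below
    ``min_length`` or beyond the genome), and ``rc_fraction`` of reads are
    reverse-complemented after the error process.
    """
    if not sources:
        raise ValueError("no source genomes")
    params.validate()
    rng = np.random.default_rng([params.seed, 2])
    genomes = [_from_str(s.sequence) for s in sources]
    reads: list[SimRead] = []
    for i in range(params.n_reads):
        src_idx = int(rng.integers(len(sources)))
        genome = genomes[src_idx]
        while True:
            length = int(round(rng.normal(params.length_mean, params.length_sd)))
            if params.min_length <= length <= len(genome):
                break
        start = int(rng.integers(len(genome) - length + 1))
        frag = _apply_errors(genome[start : start + length], params, rng)
        orientation = "+"
        if rng.random() < params.rc_fraction:
            frag = _COMP[frag][::-1]
            orientation = "-"
        src = sources[src_idx]
        reads.append(
            SimRead(
                read_id=f"{read_prefix}_{i:06d}",
                sequence=_to_str(frag),
                doc_id=src.doc_id,
                taxon_id=src.taxon_id,
                orientation=orientation,
            )
        )
    return reads


def simulate_null_reads(
    pangenome_params: PangenomeSimParams,
    read_params: ReadSimParams,
    divergence: float = 0.30,
    n_null_species: int = 5,
    read_prefix: str = "null",
) -> list[SimRead]:
    """Reads from a clade absent from the index.

    A null root is derived from the indexed root at ``divergence`` (>= 0.25
    so that homologous matches are no better than chance), null species
    descend from it at the pangenome's inter-species rate, and reads use the
    same error model.  Truth labels are ``None`` (absent from the index).
    """
    if divergence < 0.25:
        raise ValueError("null clade divergence must be >= 0.25")
    pangenome_params.validate()
    root = _root_genome(pangenome_params)
    rng = np.random.default_rng([pangenome_params.seed, 3])
    null_root = _mutate(root, divergence, rng)
    sources = [
        ReadSource(
            doc_id=None,
            taxon_id=None,
            sequence=_to_str(
                _mutate(null_root, pangenome_params.inter_species_divergence, rng)
            ),
        )
        for _ in range(n_null_species)
    ]
    return simulate_reads(sources, read_params, read_prefix=read_prefix)


def holdout_sources(
    collection: DocumentCollection, held_out: dict[int, str]
) -> list[ReadSource]:
    """Positive-read sources: the held-out genome of each indexed species."""
    return [
        ReadSource(doc_id=d, taxon_id=collection.doc_taxon[d], sequence=seq)
        for d, seq in sorted(held_out.items())
    ]
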