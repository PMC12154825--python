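"""Taxonomy tree: loading, lowest common ancestors, rank projection.

The primary on-disk format is a 4-column TSV (``id  parent_id  rank  name``)
with the root pointing to itself; NCBI-style ``nodes.dmp`` (``|``-delimited)
is accepted behind a dialect flag.  Unranked intermediate nodes are allowed;
projecting a node to a rank missing from its lineage yields ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

RANK_ORDER = [
    "species", "genus", "family", "order", "class", "phylum", "kingdom",
    "domain",
]


@dataclass
class TaxonomyTree:
    nodes: dict[int, tuple[int, str, str]]  # id -> (parent, rank, name)
    root: int
    _depth: dict[int, int] = field(default_factory=dict, repr=False)

    def parent(self, node: int) -> int:
        return self.nodes[node][0]

    def rank(self, node: int) -> str:
        return self.nodes[node][1]

    def name(self, node: int) -> str:
        return self.nodes[node][2]

    def depth(self, node: int) -> int:
        d = self._depth.get(node)
        if d is None:
            d = 0 if node == self.root else self.depth(self.parent(node)) + 1
            self._depth[node] = d
        return d

    def lineage(self, node: int) -> list[int]:
        """Path from the node up to (and including) the root."""
        path = [node]
        while node != self.root:
            node = self.parent(node)
            path.append(node)
        return path

    def is_ancestor(self, anc: int, node: int) -> bool:
        """True when ``anc`` is an ancestor of (or equal to) ``node``."""
        while True:
            if node == anc:
                return True
            if node == self.root:
                return False
            node = self.parent(node)


def _validate(nodes: dict[int, tuple[int, str, str]]) -> int:
    roots = [i for i, (p, _, _) in nodes.items() if p == i]
    if len(roots) != 1:
        raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
    root = roots[0]
    for i, (p, _, _) in nodes.items():
        if p not in nodes:
            raise ValueError(f"node {i} has unknown parent {p}")
    # cycle check by parent chasing with a step bound
    for i in nodes:
        seen = 0
        node = i
        while node != root:
            node = nodes[node][0]
            seen += 1
            if seen > len(nodes):
                raise ValueError(f"cycle detected while resolving node {i}")
    return root


def load_taxonomy(path, dialect: str = "tsv") -> TaxonomyTree:
    """Load a taxonomy from TSV (default) or NCBI nodes.dmp (``dialect='ncbi'``).

    nodes.dmp carries no names; nodes are named ``taxid_<id>``.
    """
    nodes: dict[int, tuple[int, str, str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if dialect == "ncbi":
                fields = [f.strip() for f in line.split("|")]
                if len(fields) < 3:
                    raise ValueError(f"{path}:{line_no}: malformed nodes.dmp row")
                nid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
                name = f"taxid_{nid}"
            else:
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{line_no}: expected 4 tab-separated columns")
                nid, parent, rank, name = int(fields[0]), int(fields[1]), fields[2], fields[3]
            nodes[nid] = (parent, rank, name)
    if not nodes:
        raise ValueError(f"{path}: empty taxonomy")
    root = _validate(nodes)
    return TaxonomyTree(nodes=nodes, root=root)


def build_taxonomy(rows: Iterable[tuple[int, int, str, str]]) -> TaxonomyTree:
    """Construct a tree from (id, parent, rank, name) rows in memory."""
    nodes = {int(i): (int(p), r, n) for i, p, r, n in rows}
    root = _validate(nodes)
    return TaxonomyTree(nodes=nodes, root=root)


def lca(tree: TaxonomyTree, node_ids: Iterable[int]) -> int:
    """Deepest node ancestral to (or equal to) every input node."""
    ids = list(node_ids)
    if not ids:
        raise ValueError("LCA of an empty set is undefined")
    current = ids[0]
    for other in ids[1:]:
        a, b = current, other
        da, db = tree.depth(a), tree.depth(b)
        while da > db:
            a = tree.parent(a)
            da -= 1
        while db > da:
            b = tree.parent(b)
            db -= 1
        while a != b:
            a = tree.parent(a)
            b = tree.parent(b)
        current = a
    return current


def ancestor_at_rank(tree: TaxonomyTree, node: int, rank: str) -> Optional[int]:
    """The unique ancestor-or-self of ``node`` at ``rank``; ``None`` when the
    lineage skips that rank (including when the node sits above it)."""
    if rank not in RANK_ORDER:
        raise ValueError(f"unknown rank {rank!r}")
    for anc in tree.lineage(node):
        if tree.rank(anc) == rank:
            return anc
    return None
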