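"""Taxonomy tree with rank-labelled nodes, MRCA queries, and NCBI-dialect IO.

The tree is the backbone of LCA assignment: every reference sequence carries a
taxid, and a query whose similarity neighbourhood spans several taxa is
assigned to the most recent common ancestor of that neighbourhood.

Nodes are stored as ``taxid -> (parent_taxid, rank, name)``.  The root is its
own parent, following the NCBI taxonomy dump convention (node 1 in the real
dump).  ``nodes.dmp`` / ``names.dmp`` readers and writers use the NCBI column
order with ``\\t|\\t`` separators, so real dumps and simulated dumps are read
by the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

DEFAULT_RANKS: tuple[str, ...] = (
    "superkingdom", "kingdom", "phylum", "class",
    "order", "family", "genus", "species",
)


@dataclass(frozen=True)
class TaxNode:
    taxid: int
    parent: int
    rank: str
    name: str


class TaxonomyError(ValueError):
    pass


class TaxonomyTree:
    """Rooted taxonomy with parent links and rank labels."""

    def __init__(self, nodes: Iterable[TaxNode]):
        self.nodes: dict[int, TaxNode] = {n.taxid: n for n in nodes}
        roots = [t for t, n in self.nodes.items() if n.parent == t]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        # validate connectivity
        for t in self.nodes:
            self.lineage(t)

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def rank(self, taxid: int) -> str:
        return self._get(taxid).rank

    def name(self, taxid: int) -> str:
        return self._get(taxid).name

    def parent(self, taxid: int) -> int:
        return self._get(taxid).parent

    def _get(self, taxid: int) -> TaxNode:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise TaxonomyError(f"unknown taxid: {taxid}") from None

    def lineage(self, taxid: int) -> list[int]:
        """Path from the root down to ``taxid``, inclusive."""
        path = [taxid]
        seen = {taxid}
        node = self._get(taxid)
        while node.parent != node.taxid:
            nxt = node.parent
            if nxt in seen:
                raise TaxonomyError(f"cycle at taxid {taxid}")
            path.append(nxt)
            seen.add(nxt)
            node = self._get(nxt)
        path.reverse()
        return path

    def mrca(self, taxids: Sequence[int]) -> int:
        """Most recent common ancestor of a non-empty set of taxids.

        The deepest node lying on the root path of every input taxid.
        """
        taxids = list(taxids)
        if not taxids:
            raise TaxonomyError("mrca of empty taxid set")
        common = set(self.lineage(taxids[0]))
        for t in taxids[1:]:
            common &= set(self.lineage(t))
        # deepest member of the shared ancestry: walk one lineage backwards
        for t in reversed(self.lineage(taxids[0])):
            if t in common:
                return t
        raise TaxonomyError("disconnected tree")  # pragma: no cover

    def is_ancestor(self, ancestor: int, taxid: int) -> bool:
        """True if ``ancestor`` is on the root path of ``taxid`` (inclusive)."""
        return ancestor in self.lineage(taxid)

    def leaves(self, rank: str | None = None) -> list[int]:
        parents = {n.parent for n in self.nodes.values() if n.parent != n.taxid}
        out = [t for t in self.nodes if t not in parents]
        if rank is not None:
            out = [t for t in out if self.nodes[t].rank == rank]
        return sorted(out)

    def descendants(self, taxid: int) -> set[int]:
        """All taxids in the subtree rooted at ``taxid`` (inclusive)."""
        self._get(taxid)
        children: dict[int, list[int]] = {}
        for n in self.nodes.values():
            if n.parent != n.taxid:
                children.setdefault(n.parent, []).append(n.taxid)
        out = {taxid}
        stack = [taxid]
        while stack:
            for c in children.get(stack.pop(), ()):
                out.add(c)
                stack.append(c)
        return out

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """Ancestor of ``taxid`` at a given rank, or None if absent."""
        for t in self.lineage(taxid):
            if self.nodes[t].rank == rank:
                return t
        return None

    # ---- NCBI-dialect dump IO -------------------------------------------

    def write_dump(self, outdir: str | Path) -> None:
        """Write nodes.dmp / names.dmp in the NCBI column dialect."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "nodes.dmp", "w") as fh:
            for t in sorted(self.nodes):
                n = self.nodes[t]
                fh.write(f"{t}\t|\t{n.parent}\t|\t{n.rank}\t|\n")
        with open(outdir / "names.dmp", "w") as fh:
            for t in sorted(self.nodes):
                n = self.nodes[t]
                fh.write(f"{t}\t|\t{n.name}\t|\t\t|\tscientific name\t|\n")

    @classmethod
    def read_dump(cls, taxdir: str | Path) -> "TaxonomyTree":
        taxdir = Path(taxdir)
        ranks: dict[int, tuple[int, str]] = {}
        with open(taxdir / "nodes.dmp") as fh:
            for line in fh:
                fields = [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]
                taxid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
                ranks[taxid] = (parent, rank)
        names: dict[int, str] = {}
        with open(taxdir / "names.dmp") as fh:
            for line in fh:
                fields = [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]
                taxid, name = int(fields[0]), fields[1]
                name_class = fields[3] if len(fields) > 3 else "scientific name"
                if name_class == "scientific name" or taxid not in names:
                    names[taxid] = name
        nodes = [
            TaxNode(t, parent, rank, names.get(t, f"taxid_{t}"))
            for t, (parent, rank) in ranks.items()
        ]
        return cls(nodes)
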