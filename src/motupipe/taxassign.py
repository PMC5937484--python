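"""Best-hit / equal-similarity-set LCA taxonomic assignment.

The assignment logic mirrors the tree-based approach used with local
reference databases: for a query (a MOTU representative), find the best hit
in the database, then build the set of database sequences at least as
similar *to the best hit* as the query itself is, and assign the query to
the most recent common ancestor of that whole set.  The assigned rank
therefore floats with the query's similarity and the local density of the
database — a perfect, unique match lands on a species; a mediocre match in
a sparse neighbourhood lands on a genus, family, or higher.

Identity is the same matches-over-global-alignment-length metric used by the
clusterer, so thresholds are comparable across stages.  Ties at the best hit
are handled conservatively: every tied record seeds the candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .align import global_identity
from .config import Marker, get_marker
from .motu import MOTU, MOTUTable
from .refdb import RefRecord
from .taxonomy import TaxonomyTree


class TaxAssignError(ValueError):
    pass


@dataclass
class Assignment:
    motu_id: str
    best_identity: float
    best_hit_id: str
    assigned_taxid: int
    assigned_rank: str
    scientific_name: str


def mrca(taxids: Sequence[int], tree: TaxonomyTree) -> int:
    """Most recent common ancestor of a set of taxids (deepest shared node)."""
    return tree.mrca(taxids)


def lca_assign(query: str, refdb: Sequence[RefRecord], tree: TaxonomyTree,
               motu_id: str = "", min_identity: float | None = None
               ) -> Assignment:
    """Assign one query sequence against a reference collection.

    Candidate set S = every record whose identity to the best hit is at
    least the query's identity to the best hit; the assignment is
    mrca(taxids of S).  With ``min_identity`` set, queries whose best
    identity falls below it are assigned to the root (effectively
    unassigned); by default there is no floor, matching the practice of
    keeping low-identity phylum-level assignments.
    """
    if not refdb:
        raise TaxAssignError("empty reference database")
    idents = [global_identity(query, r.seq) for r in refdb]
    best = max(idents)
    best_hits = [r for r, d in zip(refdb, idents) if d == best]

    if min_identity is not None and best < min_identity:
        root = tree.root
        return Assignment(motu_id, best, best_hits[0].record_id, root,
                          tree.rank(root), tree.name(root))

    candidate_taxids: set[int] = {r.taxid for r in best_hits}
    for bh in best_hits:
        for r in refdb:
            if r is bh or r.taxid in candidate_taxids:
                continue
            if global_identity(bh.seq, r.seq) >= best:
                candidate_taxids.add(r.taxid)
    taxid = tree.mrca(sorted(candidate_taxids))
    return Assignment(motu_id, best, best_hits[0].record_id, taxid,
                      tree.rank(taxid), tree.name(taxid))


def assign_motus(motus_or_table: Sequence[MOTU] | MOTUTable,
                 refdb: Sequence[RefRecord], tree: TaxonomyTree,
                 min_identity: float | None = None) -> dict[str, Assignment]:
    """LCA-assign every MOTU representative; fills ``MOTUTable.assignments``
    in place when given a table."""
    if isinstance(motus_or_table, MOTUTable):
        items = [(m, motus_or_table.representatives[m])
                 for m in motus_or_table.motu_ids]
    else:
        items = [(m.motu_id, m.representative) for m in motus_or_table]
    out = {mid: lca_assign(rep, refdb, tree, motu_id=mid,
                           min_identity=min_identity)
           for mid, rep in items}
    if isinstance(motus_or_table, MOTUTable):
        motus_or_table.assignments.update(out)
    return out


def merge_species(table: MOTUTable, assignments: Mapping[str, Assignment],
                  marker: str | Marker) -> MOTUTable:
    """Merge MOTUs assigned to the same species-rank taxon (COI policy only).

    Counts are summed; the representative (and motu_id) of the most abundant
    member is kept.  For 18S the table is returned unchanged: identical 18S
    sequences routinely collapse distinct species, so merging would
    compound reference-database gaps rather than fix oversplitting.
    """
    mk = get_marker(marker) if isinstance(marker, str) else marker
    if not mk.merge_same_species:
        return table
    groups: dict[int, list[str]] = {}
    for mid in table.motu_ids:
        a = assignments.get(mid)
        if a is not None and a.assigned_rank == "species":
            groups.setdefault(a.assigned_taxid, []).append(mid)

    counts = table.counts.copy()
    reps = dict(table.representatives)
    assigns = dict(table.assignments)
    drop: list[str] = []
    for taxid, mids in sorted(groups.items()):
        if len(mids) < 2:
            continue
        totals = counts.loc[mids].sum(axis=1)
        keep = totals.sort_values(ascending=False, kind="stable").index[0]
        others = [m for m in mids if m != keep]
        counts.loc[keep] += counts.loc[others].sum(axis=0)
        drop.extend(others)
    counts = counts.drop(index=drop)
    for m in drop:
        reps.pop(m, None)
        assigns.pop(m, None)
    return MOTUTable(counts, reps, assigns)


def summarize_ranks(assignments: Mapping[str, Assignment], tree: TaxonomyTree,
                    ranks: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-rank counts of distinct taxa and of MOTUs assigned at-or-below.

    A MOTU counts toward rank r when its assigned taxon has an ancestor (or
    is itself) at rank r; the distinct-taxa count at r is over those
    ancestors.  The result carries the fraction of MOTUs assigned at
    phylum-or-lower in ``df.attrs["phylum_or_lower_fraction"]``.
    """
    from .taxonomy import DEFAULT_RANKS

    ranks = list(ranks or DEFAULT_RANKS)
    per_rank_taxa: dict[str, set[int]] = {r: set() for r in ranks}
    per_rank_motus: dict[str, int] = {r: 0 for r in ranks}
    n_phylum_or_lower = 0
    rank_pos = {r: i for i, r in enumerate(ranks)}
    phylum_pos = rank_pos.get("phylum")
    for a in assignments.values():
        lineage = tree.lineage(a.assigned_taxid)
        ranks_on_path = {tree.rank(t): t for t in lineage}
        deepest = max((rank_pos[r] for r in ranks_on_path if r in rank_pos),
                      default=None)
        for r in ranks:
            if r in ranks_on_path:
                per_rank_taxa[r].add(ranks_on_path[r])
                per_rank_motus[r] += 1
        if phylum_pos is not None and deepest is not None and deepest >= phylum_pos:
            n_phylum_or_lower += 1
    df = pd.DataFrame({
        "rank": ranks,
        "n_taxa": [len(per_rank_taxa[r]) for r in ranks],
        "n_motus_assigned": [per_rank_motus[r] for r in ranks],
    })
    n = len(assignments)
    df.attrs["phylum_or_lower_fraction"] = (n_phylum_or_lower / n) if n else 0.0
    return df


def marker_taxa_overlap(assign_a: Mapping[str, Assignment],
                        assign_b: Mapping[str, Assignment],
                        tree: TaxonomyTree,
                        ranks: Sequence[str] | None = None) -> pd.DataFrame:
    """Shared / exclusive distinct taxa per rank between two markers."""
    from .taxonomy import DEFAULT_RANKS

    ranks = list(ranks or DEFAULT_RANKS)

    def taxa_at(assignments: Mapping[str, Assignment], rank: str) -> set[int]:
        out = set()
        for a in assignments.values():
            t = tree.ancestor_at_rank(a.assigned_taxid, rank)
            if t is not None:
                out.add(t)
        return out

    rows = []
    for r in ranks:
        ta, tb = taxa_at(assign_a, r), taxa_at(assign_b, r)
        rows.append({"rank": r, "shared": len(ta & tb),
                     "only_a": len(ta - tb), "only_b": len(tb - ta)})
    return pd.DataFrame(rows)


def write_assignments_tsv(assignments: Mapping[str, Assignment],
                          tree: TaxonomyTree, path: str | Path) -> None:
    rows = []
    for mid, a in assignments.items():
        lineage = ";".join(tree.name(t) for t in tree.lineage(a.assigned_taxid))
        rows.append({"motu_id": mid, "best_identity": round(a.best_identity, 6),
                     "taxid": a.assigned_taxid, "rank": a.assigned_rank,
                     "name": a.scientific_name, "lineage": lineage})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
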