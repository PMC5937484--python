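"""Dataset curation: the ordered filter chain applied after assignment.

Order matters and follows the pipeline's design:

1. **blank filter** — a MOTU whose blank/negative-control reads exceed 10%
   of its total is treated as lab contamination and removed entirely; the
   control columns are dropped afterwards;
2. **tag-switch abundance renormalization** — per MOTU, samples are sorted
   by ascending count and zeroed while the running cumulative (including
   the candidate sample) stays strictly below 3% of the MOTU total: random
   cross-talk puts a thin smear of reads into many wrong samples, and this
   removes the smear while barely touching genuine occurrences;
3. **minimal relative-abundance filter** — a MOTU is kept only if its
   relative abundance exceeds 0.01% in at least one sample, with sample
   totals recomputed after the previous steps;
4. **non-target removal** — MOTUs assigned to the root of the taxonomy or
   outside the eukaryote subtree are removed;
5. **failed samples** — sample columns with fewer than 10,000 reads in the
   final table are deleted.

All boundary semantics are strict as stated: ``> 10%``, cumulative
``< 3%``, ``> 0.01%``, ``< 10,000``.  The FilterReport reconciles read
totals exactly at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .motu import MOTUError, MOTUTable
from .taxassign import Assignment
from .taxonomy import TaxonomyTree


@dataclass
class FilterStep:
    name: str
    reads_in: int
    reads_out: int
    motus_removed: int = 0
    reads_zeroed: int = 0
    samples_dropped: int = 0
    detail: str = ""

    @property
    def reads_removed(self) -> int:
        return self.reads_in - self.reads_out


@dataclass
class FilterReport:
    steps: list[FilterStep] = field(default_factory=list)

    def add(self, step: FilterStep) -> None:
        self.steps.append(step)

    def reconciles(self) -> bool:
        """Each step's bookkeeping must match its marginals exactly, and
        consecutive steps must chain."""
        for s in self.steps:
            if s.reads_in - s.reads_out != s.reads_removed:
                return False
        for a, b in zip(self.steps, self.steps[1:]):
            if a.reads_out != b.reads_in:
                return False
        return True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def blank_filter(table: MOTUTable, control_sample_ids: Sequence[str],
                 threshold: float = 0.10,
                 report: FilterReport | None = None) -> MOTUTable:
    """Remove MOTUs whose control-sample share of total reads exceeds
    ``threshold``; control columns are dropped from the output."""
    controls = list(control_sample_ids)
    unknown = set(controls) - set(table.sample_ids)
    if unknown:
        raise MOTUError(f"unknown control sample ids: {sorted(unknown)}")
    reads_in = table.total_reads
    counts = table.counts
    totals = counts.sum(axis=1)
    in_controls = counts[controls].sum(axis=1) if controls else 0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, in_controls / totals, 0.0)
    keep = totals.index[frac <= threshold]
    removed = len(counts.index) - len(keep)
    out_counts = counts.loc[keep].drop(columns=controls)
    out = MOTUTable(out_counts,
                    {m: table.representatives[m] for m in keep},
                    {m: a for m, a in table.assignments.items() if m in set(keep)})
    if report is not None:
        report.add(FilterStep("blank_filter", reads_in, out.total_reads,
                              motus_removed=removed,
                              samples_dropped=len(controls),
                              detail=f"threshold={threshold}"))
    return out


def renormalize_tag_switching(table: MOTUTable, cum_fraction: float = 0.03,
                              report: FilterReport | None = None) -> MOTUTable:
    """Zero, per MOTU, the ascending-count samples whose running cumulative
    (candidate included) stays strictly below ``cum_fraction`` of the MOTU
    total.  Ties in the ascending sort are broken by sample id so zeroing is
    deterministic."""
    reads_in = table.total_reads
    counts = table.counts.copy()
    arr = counts.to_numpy()
    sample_ids = np.array(counts.columns)
    zeroed = 0
    for i in range(arr.shape[0]):
        row = arr[i]
        total = row.sum()
        if total == 0:
            continue
        limit = cum_fraction * total
        order = np.lexsort((sample_ids, row))  # ascending count, ties by id
        cum = 0
        for j in order:
            if row[j] == 0:
                continue
            cum += row[j]
            if cum < limit:
                zeroed += int(row[j])
                row[j] = 0
            else:
                break
    out = MOTUTable(pd.DataFrame(arr, index=counts.index, columns=counts.columns),
                    table.representatives, table.assignments)
    if report is not None:
        report.add(FilterStep("renormalize_tag_switching", reads_in,
                              out.total_reads, reads_zeroed=zeroed,
                              detail=f"cum_fraction={cum_fraction}"))
    return out


def min_relative_abundance_filter(table: MOTUTable, min_frac: float = 0.0001,
                                  report: FilterReport | None = None
                                  ) -> MOTUTable:
    """Keep a MOTU iff its count/sample-total exceeds ``min_frac`` in at
    least one sample; zero-total samples are excluded from the maximum."""
    reads_in = table.total_reads
    counts = table.counts
    totals = counts.sum(axis=0)
    nonzero = totals[totals > 0].index
    if len(nonzero) == 0:
        keep = counts.index[:0]
    else:
        rel = counts[nonzero] / totals[nonzero]
        keep = counts.index[(rel > min_frac).any(axis=1)]
    out = table.subset_motus(list(keep))
    if report is not None:
        report.add(FilterStep("min_relative_abundance", reads_in,
                              out.total_reads,
                              motus_removed=len(counts.index) - len(keep),
                              detail=f"min_frac={min_frac}"))
    return out


def remove_nontarget(table: MOTUTable, assignments: Mapping[str, Assignment],
                     tree: TaxonomyTree, target_name: str = "Eukaryota",
                     report: FilterReport | None = None) -> MOTUTable:
    """Remove MOTUs assigned to the taxonomy root or outside the target
    (eukaryote) subtree.  MOTUs without an assignment are kept."""
    reads_in = table.total_reads
    target_ids = [t for t, n in tree.nodes.items() if n.name == target_name]
    target_set: set[int] = set()
    for t in target_ids:
        target_set |= tree.descendants(t)
    keep = []
    for mid in table.motu_ids:
        a = assignments.get(mid)
        if a is None:
            keep.append(mid)
            continue
        if a.assigned_taxid == tree.root:
            continue
        if target_set and a.assigned_taxid not in target_set:
            continue
        keep.append(mid)
    out = table.subset_motus(keep)
    if report is not None:
        report.add(FilterStep("remove_nontarget", reads_in, out.total_reads,
                              motus_removed=len(table.motu_ids) - len(keep),
                              detail=f"target={target_name}"))
    return out


def drop_failed_samples(table: MOTUTable, min_reads: int = 10_000,
                        report: FilterReport | None = None) -> MOTUTable:
    """Delete sample columns with fewer than ``min_reads`` total reads."""
    reads_in = table.total_reads
    totals = table.counts.sum(axis=0)
    keep = [s for s in table.sample_ids if totals[s] >= min_reads]
    out = MOTUTable(table.counts[keep], table.representatives, table.assignments)
    if report is not None:
        report.add(FilterStep("drop_failed_samples", reads_in, out.total_reads,
                              samples_dropped=len(table.sample_ids) - len(keep),
                              detail=f"min_reads={min_reads}"))
    return out


def run_curation_chain(table: MOTUTable,
                       assignments: Mapping[str, Assignment],
                       control_sample_ids: Sequence[str],
                       tree: TaxonomyTree | None = None,
                       config: PipelineConfig | None = None
                       ) -> tuple[MOTUTable, FilterReport]:
    """Apply the five curation filters in their stated order.

    ``tree`` may be omitted when no assignments are taxonomy-resolvable (the
    non-target step is then skipped with a zero-effect report entry).
    """
    cfg = config or PipelineConfig()
    report = FilterReport()
    t = blank_filter(table, control_sample_ids, cfg.blank_fraction, report)
    t = renormalize_tag_switching(t, cfg.renorm_cum_fraction, report)
    t = min_relative_abundance_filter(t, cfg.min_rel_abundance, report)
    if tree is not None:
        t = remove_nontarget(t, assignments, tree, report=report)
    else:
        report.add(FilterStep("remove_nontarget", t.total_reads, t.total_reads,
                              detail="skipped: no taxonomy"))
    t = drop_failed_samples(t, cfg.min_sample_reads, report)
    return t, report
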