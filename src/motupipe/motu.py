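"""Chimera flagging, greedy MOTU clustering, pruning, and table assembly.

The de-novo chimera rule follows the abundance-skew logic of uchime-style
detectors: working through unique sequences in decreasing abundance, a
sequence is flagged when two already-accepted sequences, each at least
``min_parent_skew`` times as abundant, can be glued at a single breakpoint
such that each side matches its parent nearly perfectly while the full
sequence matches neither parent that well.  Genuine biological sequences are
processed before anything that could be their chimera, so the parents
themselves are never flagged.

MOTU delimitation is an abundance-greedy threshold clusterer: seeds are
taken in decreasing abundance (ties broken by lexicographic sequence), and
each sequence joins the first seed whose global-alignment identity reaches
the threshold, else founds a new MOTU.  This is a deliberate, documented
stand-in for Bayesian clustering (CROP); the CROP lower/upper parameters are
carried in the configuration for provenance but no Bayesian model is run,
because every downstream filter and statistic is clustering-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import seq_to_bytes
from .align import global_identity
from .config import Marker, get_marker
from .readprep import UniqueSeq
from .samples import SampleSheet


class MOTUError(ValueError):
    pass


@dataclass
class MOTU:
    motu_id: str
    representative: str
    members: list[UniqueSeq]

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.members:
            for sid, n in m.counts.items():
                out[sid] = out.get(sid, 0) + n
        return out

    @property
    def total(self) -> int:
        return sum(m.total for m in self.members)


# ---------------------------------------------------------------------------
# chimera detection
# ---------------------------------------------------------------------------

class _ParentPool:
    """Accepted sequences of one length, abundance-ordered, as a byte matrix."""

    def __init__(self, length: int, capacity: int):
        self.mat = np.empty((capacity, length), dtype=np.uint8)
        self.totals = np.empty(capacity, dtype=np.int64)
        self.size = 0

    def append(self, seq: np.ndarray, total: int) -> None:
        self.mat[self.size] = seq
        self.totals[self.size] = total
        self.size += 1

    def eligible(self, min_total: float) -> int:
        # totals are non-increasing, so the eligible parents are a prefix
        return int(np.searchsorted(-self.totals[:self.size], -min_total,
                                   side="right"))


def detect_chimeras(uniques: Sequence[UniqueSeq], min_parent_skew: float = 2.0,
                    segment_identity: float = 0.99) -> list[bool]:
    """Flag likely PCR chimeras among abundance-sorted unique sequences.

    Returns one flag per input, in input order.  The input must be sorted by
    decreasing abundance (as :func:`motupipe.readprep.dereplicate` emits);
    each candidate is tested against all previously accepted sequences with
    abundance >= ``min_parent_skew`` times its own: it is flagged when some
    breakpoint splits it into a left segment matching one such parent and a
    right segment matching another, each at >= ``segment_identity``, while
    the full sequence matches neither parent that well.  Only same-length
    parents enter the positionwise test — the simulator's substitution-only
    model keeps template lengths aligned, and length mismatches would
    require a gapped segment model for little gain.  The scan is vectorised
    over the whole parent pool per candidate.
    """
    n = len(uniques)
    flags = [False] * n
    pools: dict[int, _ParentPool] = {}
    for i, u in enumerate(uniques):
        q = seq_to_bytes(u.seq)
        L = q.size
        pool = pools.get(L)
        if pool is not None and pool.size:
            j = pool.eligible(min_parent_skew * u.total)
            if j > 0:
                sub = pool.mat[:j]
                cum = np.cumsum(sub != q, axis=1)          # j x L mismatch prefix
                tot = cum[:, -1]
                # parents the query effectively *is* cannot serve as evidence
                valid = tot > (1.0 - segment_identity) * L
                if valid.any():
                    b = np.arange(1, L)                    # interior breakpoints
                    budget_l = (1.0 - segment_identity) * b
                    budget_r = (1.0 - segment_identity) * (L - b)
                    left_ok = (cum[:, :L - 1] <= budget_l) & valid[:, None]
                    right_ok = ((tot[:, None] - cum[:, :L - 1]) <= budget_r) \
                        & valid[:, None]
                    # a single parent can never pass both sides at one
                    # breakpoint (its segment budgets sum to the full budget
                    # it already exceeded), so any joint hit is a two-parent
                    # crossover signature
                    flags[i] = bool(np.any(left_ok.any(axis=0)
                                           & right_ok.any(axis=0)))
        if not flags[i]:
            if pool is None:
                pool = pools[L] = _ParentPool(L, n)
            pool.append(q, u.total)
    return flags


def remove_chimeras(uniques: Sequence[UniqueSeq], min_parent_skew: float = 2.0,
                    segment_identity: float = 0.99
                    ) -> tuple[list[UniqueSeq], int]:
    flags = detect_chimeras(uniques, min_parent_skew, segment_identity)
    kept = [u for u, f in zip(uniques, flags) if not f]
    return kept, sum(flags)


# ---------------------------------------------------------------------------
# greedy clustering
# ---------------------------------------------------------------------------

def cluster_greedy(uniques: Sequence[UniqueSeq], threshold: float) -> list[MOTU]:
    """Abundance-greedy threshold clustering into MOTUs.

    Identity is matches over global-alignment length (indels count as
    mismatches), the same metric used at assignment time.  Input order rule:
    decreasing total, ties by lexicographic sequence.  Read counts are
    conserved: the sum of MOTU totals equals the sum of input totals.
    """
    if not uniques:
        raise MOTUError("cluster_greedy needs at least one unique sequence")
    order = sorted(uniques, key=lambda u: (-u.total, u.seq))
    seeds: list[str] = []
    members: list[list[UniqueSeq]] = []
    for u in order:
        placed = False
        for k, seed in enumerate(seeds):
            # cheap length prescreen: identity can never reach the threshold
            # if lengths differ more than the allowed mismatch budget
            if abs(len(seed) - len(u.seq)) > (1 - threshold) * max(len(seed), len(u.seq)):
                continue
            if global_identity(u.seq, seed) >= threshold:
                members[k].append(u)
                placed = True
                break
        if not placed:
            seeds.append(u.seq)
            members.append([u])
    motus = []
    for k, mem in enumerate(members):
        motus.append(MOTU(motu_id=f"motu_{k + 1:05d}", representative=mem[0].seq,
                          members=mem))
    return motus


def prune_low_abundance_motus(motus: Sequence[MOTU], marker: str | Marker,
                              min_reads: int | None = None) -> list[MOTU]:
    """Remove MOTUs with fewer than ``min_reads`` total reads (COI policy:
    fewer than five reads after clustering; skipped for 18S)."""
    mk = get_marker(marker) if isinstance(marker, str) else marker
    threshold = mk.min_motu_reads if min_reads is None else min_reads
    if threshold <= 0:
        return list(motus)
    return [m for m in motus if m.total >= threshold]


# ---------------------------------------------------------------------------
# MOTU table
# ---------------------------------------------------------------------------

class MOTUTable:
    """MOTU x sample count matrix plus representatives and assignments.

    ``counts`` is a pandas DataFrame indexed by motu_id with one integer
    column per sample; ``representatives`` maps motu_id to its most abundant
    member sequence; ``assignments`` (filled by the taxonomic-assignment
    stage) maps motu_id to an Assignment.
    """

    def __init__(self, counts: pd.DataFrame, representatives: dict[str, str],
                 assignments: dict[str, object] | None = None):
        if counts.columns.duplicated().any():
            raise MOTUError("duplicate sample ids in MOTU table")
        if counts.index.duplicated().any():
            raise MOTUError("duplicate motu ids in MOTU table")
        if (counts.to_numpy() < 0).any():
            raise MOTUError("negative counts in MOTU table")
        self.counts = counts.astype(np.int64)
        self.representatives = dict(representatives)
        self.assignments = dict(assignments or {})

    @property
    def motu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def copy(self) -> "MOTUTable":
        return MOTUTable(self.counts.copy(), self.representatives,
                         self.assignments)

    def subset_motus(self, motu_ids: Sequence[str]) -> "MOTUTable":
        keep = [m for m in self.counts.index if m in set(motu_ids)]
        return MOTUTable(self.counts.loc[keep],
                         {m: self.representatives[m] for m in keep},
                         {m: a for m, a in self.assignments.items() if m in set(keep)})

    def write_tsv(self, path: str | Path) -> None:
        df = self.counts.copy()
        df.insert(0, "representative", [self.representatives.get(m, "")
                                        for m in df.index])
        df.to_csv(path, sep="\t", index_label="motu_id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MOTUTable":
        df = pd.read_csv(path, sep="\t", index_col="motu_id")
        reps = df.pop("representative").to_dict() if "representative" in df else {}
        return cls(df, reps)


def build_motu_table(motus: Sequence[MOTU], sheet: SampleSheet | Sequence[str]
                     ) -> MOTUTable:
    """Assemble the MOTU x sample matrix; row sums equal MOTU totals.

    ``sheet`` may be a SampleSheet (all its sample ids become columns) or an
    explicit sequence of sample ids.  Counts for unknown sample ids raise.
    """
    if isinstance(sheet, SampleSheet):
        sample_ids = [e.sample_id for e in sheet]
    else:
        sample_ids = list(sheet)
    if len(set(sample_ids)) != len(sample_ids):
        raise MOTUError("duplicate sample ids")
    known = set(sample_ids)
    data = np.zeros((len(motus), len(sample_ids)), dtype=np.int64)
    col = {s: j for j, s in enumerate(sample_ids)}
    reps = {}
    ids = []
    for i, m in enumerate(motus):
        ids.append(m.motu_id)
        reps[m.motu_id] = m.representative
        for sid, n in m.counts.items():
            if sid not in known:
                raise MOTUError(f"count for unknown sample id {sid!r}")
            data[i, col[sid]] += n
    counts = pd.DataFrame(data, index=pd.Index(ids, name="motu_id"),
                          columns=sample_ids)
    return MOTUTable(counts, reps)
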