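"""Read preparation: trim, merge, demultiplex, length-filter, dereplicate.

This stage turns raw tagged paired-end amplicon reads into per-sample
dereplicated sequences:

1. each mate is trimmed from the 3' end to the longest prefix whose median
   Phred quality exceeds a threshold (3' decay being the dominant Illumina
   failure mode);
2. mates are merged over their best 3' overlap, scored by a quality-weighted
   match/mismatch tally (the +-1 per column, scaled by mean column quality
   over 40, re-specification of a paired-end alignment quality score);
3. merged reads are demultiplexed on exact 8-nt inline tags present at
   *both* ends — a read whose two ends carry different known tags is an
   inter-sample chimera and is rejected, which is precisely what the
   dual-identical-tag library design exists to catch; primers are matched
   with a small IUPAC/inosine-aware mismatch allowance and stripped;
4. inserts outside the marker's length window are dropped;
5. surviving inserts are dereplicated into unique sequences with per-sample
   counts (and, for the 18S policy only, singletons are removed).

Every input read ends up in exactly one class (assigned or rejected with a
reason), so class counts always sum to the input count.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from ._seq import ascii_to_phred, count_mismatches, revcomp, seq_to_bytes
from .config import Marker, PipelineConfig, get_marker
from .samples import SampleSheet

REJECT_REASONS = ("low_quality", "merge_failed", "unknown_tag",
                  "tag_pair_mismatch", "primer_mismatch", "too_short",
                  "length_filter")


class ReadPrepError(ValueError):
    pass


@dataclass
class ReadPair:
    read_id: str
    seq_fwd: str
    qual_fwd: np.ndarray
    seq_rev: str
    qual_rev: np.ndarray

    def __post_init__(self):
        if len(self.seq_fwd) != len(self.qual_fwd) or len(self.seq_rev) != len(self.qual_rev):
            raise ReadPrepError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass
class UniqueSeq:
    """A dereplicated sequence with per-sample read counts."""

    seq: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# quality trimming
# ---------------------------------------------------------------------------

def trim_by_median_quality(seq: str, qual: Sequence[int] | np.ndarray,
                           q_threshold: int = 30) -> tuple[str, np.ndarray]:
    """Longest prefix whose median Phred quality exceeds ``q_threshold``.

    Bases are removed from the 3' end only.  Returns an empty read when no
    prefix qualifies.  The scan walks prefix lengths from the full read down,
    maintaining a quality histogram so the median is O(1) per step.
    """
    qual = np.asarray(qual, dtype=np.int64)
    if len(seq) != qual.size:
        raise ReadPrepError("sequence/quality length mismatch")
    if q_threshold < 0:
        raise ReadPrepError("q_threshold must be >= 0")
    n = qual.size
    if n == 0:
        return "", qual
    hist = np.bincount(qual, minlength=94)
    cum = np.cumsum(hist)

    def median_gt(k: int) -> bool:
        # median of first k prefix values; for even k the lower-median
        # convention is used (conservative: harder to pass)
        lo_rank = (k + 1) // 2
        hi_rank = k // 2 + 1 if k % 2 == 0 else lo_rank
        lo = int(np.searchsorted(cum, lo_rank))
        hi = int(np.searchsorted(cum, hi_rank))
        return (lo + hi) / 2 > q_threshold

    for k in range(n, 0, -1):
        if median_gt(k):
            return seq[:k], qual[:k]
        q = qual[k - 1]
        hist[q] -= 1
        cum[q:] -= 1
    return "", qual[:0]


# ---------------------------------------------------------------------------
# pair merging
# ---------------------------------------------------------------------------

@dataclass
class MergeResult:
    merged: str | None
    qual: np.ndarray | None
    score: float
    overlap: int
    accepted: bool
    reason: str = ""


def merge_pair(pair: ReadPair, min_overlap: int = 10,
               max_overlap_mismatch_frac: float = 0.25,
               min_score: float = 40.0) -> MergeResult:
    """Merge a read pair over its best 3' overlap.

    Mate 2 is reverse-complemented; every candidate overlap length from
    ``min_overlap`` to the shorter mate is scored as the sum over overlap
    columns of +1 (match) / -1 (mismatch) scaled by the mean of the two base
    qualities over 40.  The best-scoring overlap wins (ties to the longer
    overlap); the consensus takes the higher-quality base at conflicting
    columns.  Rejection (score below ``min_score``, overlap too short, or
    mismatch fraction too high) is a return state, not an error.
    """
    if not pair.seq_fwd or not pair.seq_rev:
        return MergeResult(None, None, 0.0, 0, False, "empty_mate")
    s1 = seq_to_bytes(pair.seq_fwd)
    q1 = np.asarray(pair.qual_fwd, dtype=np.float64)
    s2 = seq_to_bytes(revcomp(pair.seq_rev))
    q2 = np.asarray(pair.qual_rev, dtype=np.float64)[::-1]
    l1, l2 = s1.size, s2.size
    max_o = min(l1, l2)
    if max_o < min_overlap:
        return MergeResult(None, None, 0.0, 0, False, "merge_failed")

    best = None  # (score, o, mismatch_frac)
    for o in range(min_overlap, max_o + 1):
        a, b = s1[l1 - o:], s2[:o]
        qa, qb = q1[l1 - o:], q2[:o]
        match = a == b
        contrib = np.where(match, 1.0, -1.0) * (qa + qb) / 2.0 / 40.0
        score = float(contrib.sum())
        mm_frac = 1.0 - match.mean()
        if best is None or score > best[0] or (score == best[0] and o > best[1]):
            best = (score, o, mm_frac)
    score, o, mm_frac = best
    if score < min_score or mm_frac > max_overlap_mismatch_frac:
        return MergeResult(None, None, score, o, False, "merge_failed")

    a, b = s1[l1 - o:], s2[:o]
    qa, qb = q1[l1 - o:], q2[:o]
    take_b = qb > qa
    cons = np.where(take_b, b, a)
    cons_q = np.maximum(qa, qb)
    merged = (s1[:l1 - o].tobytes() + cons.astype(np.uint8).tobytes()
              + s2[o:].tobytes()).decode("ascii")
    qual = np.concatenate([q1[:l1 - o], cons_q, q2[o:]]).astype(np.int64)
    return MergeResult(merged, qual, score, o, True)


def merge_pairs_batch(pairs: Sequence[ReadPair], min_overlap: int = 10,
                      max_overlap_mismatch_frac: float = 0.25,
                      min_score: float = 40.0,
                      chunk: int = 20_000) -> list[MergeResult]:
    """Vectorised ``merge_pair`` over many read pairs.

    Pairs are grouped by (mate lengths, quality profile); within a group the
    per-column quality weights are shared, so scoring all candidate overlaps
    reduces to array comparisons and one matrix-vector product per overlap.
    Results are identical to calling :func:`merge_pair` on each pair.
    """
    results: list[MergeResult | None] = [None] * len(pairs)
    groups: dict[tuple, list[int]] = defaultdict(list)
    for i, p in enumerate(pairs):
        if not p.seq_fwd or not p.seq_rev:
            results[i] = MergeResult(None, None, 0.0, 0, False, "empty_mate")
            continue
        key = (len(p.seq_fwd), len(p.seq_rev),
               np.asarray(p.qual_fwd).tobytes(), np.asarray(p.qual_rev).tobytes())
        groups[key].append(i)

    for (l1, l2, q1b, q2b), idx in groups.items():
        q1 = np.frombuffer(q1b, dtype=np.asarray(pairs[idx[0]].qual_fwd).dtype).astype(np.float64)
        q2 = np.frombuffer(q2b, dtype=np.asarray(pairs[idx[0]].qual_rev).dtype).astype(np.float64)[::-1]
        max_o = min(l1, l2)
        if max_o < min_overlap:
            for i in idx:
                results[i] = MergeResult(None, None, 0.0, 0, False, "merge_failed")
            continue
        for c0 in range(0, len(idx), chunk):
            sub = idx[c0:c0 + chunk]
            n = len(sub)
            S1 = np.empty((n, l1), dtype=np.uint8)
            S2 = np.empty((n, l2), dtype=np.uint8)
            for r, i in enumerate(sub):
                S1[r] = seq_to_bytes(pairs[i].seq_fwd)
                S2[r] = seq_to_bytes(revcomp(pairs[i].seq_rev))
            best_score = np.full(n, -np.inf)
            best_o = np.zeros(n, dtype=np.int64)
            best_mm = np.zeros(n)
            for o in range(min_overlap, max_o + 1):
                m = S1[:, l1 - o:] == S2[:, :o]
                w = (q1[l1 - o:] + q2[:o]) / 80.0
                wmatch = m.astype(np.float64) @ w
                score = 2.0 * wmatch - w.sum()
                mcount = m.sum(axis=1)
                upd = (score > best_score) | ((score == best_score) & (o > best_o))
                best_score[upd] = score[upd]
                best_o[upd] = o
                best_mm[upd] = 1.0 - mcount[upd] / o
            accept = (best_score >= min_score) & (best_mm <= max_overlap_mismatch_frac)
            for r, i in enumerate(sub):
                o = int(best_o[r])
                if not accept[r]:
                    results[i] = MergeResult(None, None, float(best_score[r]),
                                             o, False, "merge_failed")
                    continue
                a, b = S1[r, l1 - o:], S2[r, :o]
                qa, qb = q1[l1 - o:], q2[:o]
                take_b = qb > qa
                cons = np.where(take_b, b, a)
                merged = (S1[r, :l1 - o].tobytes() + cons.astype(np.uint8).tobytes()
                          + S2[r, o:].tobytes()).decode("ascii")
                qual = np.concatenate([q1[:l1 - o], np.maximum(qa, qb),
                                       q2[o:]]).astype(np.int64)
                results[i] = MergeResult(merged, qual, float(best_score[r]), o, True)
    return results  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------

@dataclass
class DemuxResult:
    sample_id: str | None
    insert: str | None
    reason: str = ""
    orientation: str = "+"


def _find_end(seq: str, tags: dict[str, str], primer: str, max_mm: int,
              max_spacer: int = 4) -> tuple[str | None, int | None, str]:
    """Locate tag+primer at the 5' end of ``seq`` allowing 0-4 spacer bases.

    Returns (tag, insert_start, failure_reason); reason is "" on success.
    """
    plen = len(primer)
    saw_tag = False
    for off in range(0, max_spacer + 1):
        tag = seq[off:off + 8]
        if len(tag) < 8:
            break
        if tag not in tags:
            continue
        saw_tag = True
        window = seq[off + 8: off + 8 + plen]
        if len(window) < plen:
            continue
        if count_mismatches(primer, window) <= max_mm:
            return tag, off + 8 + plen, ""
    return None, None, ("primer_mismatch" if saw_tag else "unknown_tag")


def demultiplex(merged: str, sheet: SampleSheet, marker: str | Marker,
                max_primer_mismatch: int = 2,
                _tags: dict[str, str] | None = None) -> DemuxResult:
    """Assign a merged read to a sample via its dual inline tags.

    Skips up to four leading spacer bases at each end, requires an exact
    8-nt tag match at both ends and the *same* tag at both (mismatched known
    tags are inter-sample chimeras -> ``tag_pair_mismatch``), then matches
    the primers with at most ``max_primer_mismatch`` IUPAC-aware mismatches
    and strips spacer+tag+primer from both ends.  Both orientations are
    tried, ties resolved toward the forward orientation.
    """
    mk = get_marker(marker) if isinstance(marker, str) else marker
    tags = _tags if _tags is not None else sheet.tag_map(mk.name)
    min_len = 2 * (8 + min(len(mk.fwd_primer), len(mk.rev_primer)))
    if len(merged) < min_len:
        return DemuxResult(None, None, "too_short")

    reasons = []
    for orientation in ("+", "-"):
        seq = merged if orientation == "+" else revcomp(merged)
        tag5, ins_start, r5 = _find_end(seq, tags, mk.fwd_primer,
                                        max_primer_mismatch)
        rc = revcomp(seq)
        tag3, ins_end_rc, r3 = _find_end(rc, tags, mk.rev_primer,
                                         max_primer_mismatch)
        if tag5 is not None and tag3 is not None:
            if tag5 != tag3:
                reasons.append("tag_pair_mismatch")
                continue
            insert = seq[ins_start: len(seq) - ins_end_rc]
            if not insert:
                reasons.append("too_short")
                continue
            return DemuxResult(tags[tag5], insert, "", orientation)
        reasons.append(r5 if tag5 is None else r3)

    for r in ("tag_pair_mismatch", "primer_mismatch", "too_short"):
        if r in reasons:
            return DemuxResult(None, None, r)
    return DemuxResult(None, None, "unknown_tag")


# ---------------------------------------------------------------------------
# length filter, dereplication, singleton policy
# ---------------------------------------------------------------------------

def length_filter(inserts: Iterable[tuple[str, str]], marker: str | Marker
                  ) -> tuple[list[tuple[str, str]], int]:
    """Keep (sample_id, insert) pairs whose insert length lies in the
    marker's closed interval; returns (retained, n_removed)."""
    mk = get_marker(marker) if isinstance(marker, str) else marker
    lo, hi = mk.length_range
    kept, removed = [], 0
    for sid, ins in inserts:
        if lo <= len(ins) <= hi:
            kept.append((sid, ins))
        else:
            removed += 1
    return kept, removed


def dereplicate(inserts: Iterable[tuple[str, str]]) -> list[UniqueSeq]:
    """Exact-sequence grouping with per-sample counts.

    Output order: decreasing total, ties by lexicographic sequence — the
    deterministic ordering the downstream greedy stages rely on.
    """
    acc: dict[str, Counter] = defaultdict(Counter)
    for sid, ins in inserts:
        acc[ins][sid] += 1
    uniques = [UniqueSeq(seq, dict(sorted(cnt.items()))) for seq, cnt in acc.items()]
    uniques.sort(key=lambda u: (-u.total, u.seq))
    return uniques


def remove_singletons(uniques: Sequence[UniqueSeq], marker: str | Marker
                      ) -> list[UniqueSeq]:
    """Drop total==1 sequences when the marker policy calls for it (18S);
    for COI the input is returned unchanged — early singleton removal would
    excessively prune this long variable marker."""
    mk = get_marker(marker) if isinstance(marker, str) else marker
    if not mk.remove_singletons:
        return list(uniques)
    return [u for u in uniques if u.total >= 2]


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class ReadPrepReport:
    n_input: int = 0
    n_assigned: int = 0
    rejected: Counter = field(default_factory=Counter)
    n_length_removed: int = 0

    def conserves_reads(self) -> bool:
        return self.n_input == self.n_assigned + sum(self.rejected.values())


def iter_fastq_pairs(fq1: str | Path, fq2: str | Path) -> Iterator[ReadPair]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(fq1) as h1, open(fq2) as h2:
        for (t1, s1, q1), (t2, s2, q2) in zip(FastqGeneralIterator(h1),
                                              FastqGeneralIterator(h2)):
            yield ReadPair(t1.split()[0].removesuffix("/1"),
                           s1, ascii_to_phred(q1), s2, ascii_to_phred(q2))


def run_readprep(pairs: Iterable[ReadPair], sheet: SampleSheet,
                 marker: str | Marker, cfg: PipelineConfig | None = None
                 ) -> tuple[list[UniqueSeq], ReadPrepReport,
                            dict[str, str]]:
    """Full read-preparation chain on an iterable of read pairs.

    Returns the dereplicated uniques (marker singleton policy applied), a
    conservation report, and a read_id -> assigned sample map for
    ground-truth comparisons.
    """
    cfg = cfg or PipelineConfig()
    mk = get_marker(marker) if isinstance(marker, str) else marker
    report = ReadPrepReport()
    assigned: dict[str, str] = {}
    inserts: list[tuple[str, str]] = []

    trimmed: list[ReadPair] = []
    for pair in pairs:
        report.n_input += 1
        s1, q1 = trim_by_median_quality(pair.seq_fwd, pair.qual_fwd, cfg.trim_quality)
        s2, q2 = trim_by_median_quality(pair.seq_rev, pair.qual_rev, cfg.trim_quality)
        if not s1 or not s2:
            report.rejected["low_quality"] += 1
            continue
        trimmed.append(ReadPair(pair.read_id, s1, q1, s2, q2))

    merges = merge_pairs_batch(trimmed, cfg.min_overlap,
                               cfg.max_overlap_mismatch_frac, cfg.min_merge_score)
    tags = sheet.tag_map(mk.name)
    lo, hi = mk.length_range
    for pair, mres in zip(trimmed, merges):
        if not mres.accepted:
            report.rejected["merge_failed"] += 1
            continue
        dres = demultiplex(mres.merged, sheet, mk, cfg.max_primer_mismatch,
                           _tags=tags)
        if dres.sample_id is None:
            report.rejected[dres.reason] += 1
            continue
        if not (lo <= len(dres.insert) <= hi):
            report.rejected["length_filter"] += 1
            report.n_length_removed += 1
            continue
        report.n_assigned += 1
        assigned[pair.read_id] = dres.sample_id
        inserts.append((dres.sample_id, dres.insert))
    uniques = remove_singletons(dereplicate(inserts), mk)
    return uniques, report, assigned


def write_uniques_fasta(uniques: Sequence[UniqueSeq], path: str | Path) -> None:
    """usearch-style size-annotated FASTA, one record per (unique, sample)."""
    with open(path, "w") as fh:
        for i, u in enumerate(uniques):
            for sid, n in u.counts.items():
                fh.write(f">uniq_{i:06d};size={n};sample={sid};\n{u.seq}\n")
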