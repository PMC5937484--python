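"""In-silico PCR and reference-database construction.

Primer matching is ungapped and IUPAC/inosine-aware: a window position
matches when the template base belongs to the primer letter's base set
(inosine and N in the primer match everything).  ``in_silico_pcr`` scans both
strands of every template for a forward-primer site followed by a
reverse-complemented reverse-primer site, reporting the insert between the
two sites when its length falls in the marker window — the classic
ecoPCR-style electronic amplification used to carve marker-specific
reference databases out of bulk sequence collections.

``primer_coverage_compare`` quantifies how two primer sets differ in taxon
coverage over the same templates; for a primer set whose every position is a
degeneracy superset of another's (e.g. a re-designed forward primer with
added degenerate bases and inosines), the amplified set can only grow.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seq import (BASE_BITS, count_mismatches, is_superset_code, primer_mask,
                   revcomp, seq_to_bytes)
from .taxonomy import TaxonomyTree


class RefDBError(ValueError):
    pass


@dataclass(frozen=True)
class Primer:
    """A possibly degenerate primer (IUPAC codes plus inosine ``I``)."""

    name: str
    seq: str
    direction: str = "fwd"  # fwd | rev

    def __post_init__(self):
        if not self.seq:
            raise RefDBError("empty primer sequence")
        primer_mask(self.seq)  # validates the alphabet
        if self.direction not in ("fwd", "rev"):
            raise RefDBError(f"direction must be fwd/rev, got {self.direction!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class RefRecord:
    """A reference sequence tied to a taxonomy node."""

    record_id: str
    seq: str
    taxid: int
    source: str = "simulated"


@dataclass(frozen=True)
class Amplicon:
    record_id: str
    insert: str
    start: int      # 0-based insert start on the reported strand
    end: int        # half-open insert end
    strand: str     # "+" | "-"
    taxid: int
    fwd_mismatches: int
    rev_mismatches: int


def primer_match(primer: Primer | str, window: str) -> int:
    """Mismatch count of a primer against an equal-length window.

    Raises on length mismatch.  I/N in the primer match any base; N in the
    window matches nothing.
    """
    seq = primer.seq if isinstance(primer, Primer) else primer
    return count_mismatches(seq, window)


def _site_mismatch_profile(primer_seq: str, template: str) -> np.ndarray:
    """Mismatch count of the primer at every start position of the template.

    Vectorised sliding-window scan; positions past ``len(template)-len(primer)``
    are absent from the output.
    """
    pm = primer_mask(primer_seq)
    tb = BASE_BITS[seq_to_bytes(template)]
    if len(tb) < len(pm):
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(tb, len(pm))
    return np.count_nonzero((windows & pm) == 0, axis=1)


def _scan_strand(template: str, fwd: str, rev_rc: str, max_mm: int,
                 len_range: tuple[int, int], all_hits: bool) -> list[tuple[int, int, int, int]]:
    """(insert_start, insert_end, fwd_mm, rev_mm) tuples, non-overlapping, left-to-right."""
    lo, hi = len_range
    fmm = _site_mismatch_profile(fwd, template)
    rmm = _site_mismatch_profile(rev_rc, template)
    f_pos = np.flatnonzero(fmm <= max_mm)
    r_pos = np.flatnonzero(rmm <= max_mm)
    hits: list[tuple[int, int, int, int]] = []
    next_free = 0
    for f in f_pos:
        if f < next_free:
            continue
        ins_start = f + len(fwd)
        # reverse site must start after the insert, at distance lo..hi
        cands = r_pos[(r_pos >= ins_start + lo) & (r_pos <= ins_start + hi)]
        if cands.size == 0:
            continue
        r = int(cands[0])
        hits.append((ins_start, r, int(fmm[f]), int(rmm[r])))
        next_free = r + len(rev_rc)
        if not all_hits:
            break
    return hits


def in_silico_pcr(refs: Iterable[RefRecord], fwd: Primer, rev: Primer,
                  max_mm: int = 2, len_range: tuple[int, int] = (1, 10_000),
                  all_hits: bool = True) -> list[Amplicon]:
    """Electronic PCR of a primer pair over a reference collection.

    Both strands of each template are scanned for a forward-primer site with
    a downstream reverse-complemented reverse-primer site, each within
    ``max_mm`` mismatches; the insert (primers excluded) is reported when its
    length lies in the closed ``len_range``.  Hits on one strand are reported
    left-to-right without overlap; set ``all_hits=False`` to keep only the
    first hit per strand.
    """
    lo, hi = len_range
    if lo <= 0 or hi < lo:
        raise RefDBError(f"invalid length range {len_range}")
    rev_rc = revcomp(rev.seq)
    out: list[Amplicon] = []
    for rec in refs:
        for strand, tmpl in (("+", rec.seq), ("-", revcomp(rec.seq))):
            for s, e, fm, rm in _scan_strand(tmpl, fwd.seq, rev_rc, max_mm,
                                             (lo, hi), all_hits):
                out.append(Amplicon(rec.record_id, tmpl[s:e], s, e, strand,
                                    rec.taxid, fm, rm))
    return out


def build_refdb(amplicons: Iterable[Amplicon], taxonomy: TaxonomyTree,
                source: str = "insilico-pcr") -> tuple[list[RefRecord], pd.DataFrame]:
    """Dereplicate amplicons into reference records plus a per-phylum summary.

    Identical inserts carrying different taxids are stored once under the
    MRCA of those taxids (the same lowest-common-ancestor philosophy used at
    assignment time).  Records with taxids missing from the taxonomy are
    skipped.
    """
    by_seq: dict[str, list[int]] = defaultdict(list)
    skipped = 0
    for amp in amplicons:
        if amp.taxid not in taxonomy:
            skipped += 1
            continue
        by_seq[amp.insert].append(amp.taxid)
    records: list[RefRecord] = []
    for i, seq in enumerate(sorted(by_seq)):
        taxids = sorted(set(by_seq[seq]))
        taxid = taxids[0] if len(taxids) == 1 else taxonomy.mrca(taxids)
        records.append(RefRecord(f"ref_{i:06d}", seq, taxid, source))
    rows = []
    counts: dict[tuple[int | None, str], int] = defaultdict(int)
    for rec in records:
        phylum = taxonomy.ancestor_at_rank(rec.taxid, "phylum")
        name = taxonomy.name(phylum) if phylum is not None else "(above phylum)"
        counts[(phylum, name)] += 1
    for (phylum, name), n in sorted(counts.items(), key=lambda kv: -kv[1]):
        rows.append({"phylum_taxid": phylum, "phylum": name, "n_sequences": n})
    summary = pd.DataFrame(rows, columns=["phylum_taxid", "phylum", "n_sequences"])
    summary.attrs["skipped_unresolvable"] = skipped
    return records, summary


def primer_set_is_superset(sub_fwd: Primer, sub_rev: Primer,
                           sup_fwd: Primer, sup_rev: Primer) -> bool:
    """Per-position degeneracy superset check between two primer sets."""
    for a, b in ((sub_fwd, sup_fwd), (sub_rev, sup_rev)):
        if len(a) != len(b):
            return False
        if not all(is_superset_code(x, y) for x, y in zip(a.seq, b.seq)):
            return False
    return True


def primer_coverage_compare(refs: Sequence[RefRecord],
                            set_a: tuple[Primer, Primer],
                            set_b: tuple[Primer, Primer],
                            max_mm: int = 2,
                            len_range: tuple[int, int] = (1, 10_000),
                            taxonomy: TaxonomyTree | None = None,
                            group_rank: str = "phylum") -> pd.DataFrame:
    """Per-taxon-group amplified counts for two primer sets on one collection.

    Returns one row per group (plus a ``TOTAL`` row) with the number of
    references amplified by set A, by set B, by A only, and by B only, all at
    the same mismatch allowance.
    """
    def amplified_ids(fwd: Primer, rev: Primer) -> set[str]:
        return {a.record_id for a in in_silico_pcr(refs, fwd, rev, max_mm,
                                                   len_range, all_hits=False)}

    amp_a = amplified_ids(*set_a)
    amp_b = amplified_ids(*set_b)

    def group_of(rec: RefRecord) -> str:
        if taxonomy is None:
            return "all"
        anc = taxonomy.ancestor_at_rank(rec.taxid, group_rank)
        return taxonomy.name(anc) if anc is not None else f"(above {group_rank})"

    rows: dict[str, dict[str, int]] = defaultdict(
        lambda: {"n_refs": 0, "amplified_A": 0, "amplified_B": 0,
                 "A_only": 0, "B_only": 0})
    for rec in refs:
        g = rows[group_of(rec)]
        g["n_refs"] += 1
        in_a, in_b = rec.record_id in amp_a, rec.record_id in amp_b
        g["amplified_A"] += in_a
        g["amplified_B"] += in_b
        g["A_only"] += in_a and not in_b
        g["B_only"] += in_b and not in_a
    total = {"n_refs": len(refs), "amplified_A": len(amp_a),
             "amplified_B": len(amp_b),
             "A_only": len(amp_a - amp_b), "B_only": len(amp_b - amp_a)}
    df = pd.DataFrame([{"group": g, **v} for g, v in sorted(rows.items())]
                      + [{"group": "TOTAL", **total}])
    return df


# ---- FASTA IO with taxid annotations ------------------------------------

def write_refdb_fasta(records: Iterable[RefRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.record_id} taxid={rec.taxid}; source={rec.source};\n")
            fh.write(rec.seq + "\n")


def read_refdb_fasta(path: str | Path) -> list[RefRecord]:
    """Read a reference FASTA whose headers carry ``taxid=<int>;``."""
    records: list[RefRecord] = []
    rid, taxid, source, chunks = None, None, "unknown", []

    def flush():
        if rid is not None:
            if taxid is None:
                raise RefDBError(f"record {rid!r} lacks a taxid= annotation")
            records.append(RefRecord(rid, "".join(chunks), taxid, source))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                header = line[1:]
                rid = header.split()[0]
                taxid, source, chunks = None, "unknown", []
                for tok in header.split():
                    if tok.startswith("taxid="):
                        taxid = int(tok[6:].rstrip(";"))
                    elif tok.startswith("source="):
                        source = tok[7:].rstrip(";")
            elif line:
                chunks.append(line.strip().upper())
    flush()
    return records
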