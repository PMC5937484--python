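"""Sample sheet: inline-tag to sample mapping with community metadata.

Each sequencing library pools many samples, distinguished by an 8-nt tag
ligated to *both* primers of a pair (dual identical tags).  A read whose two
ends carry different known tags is an inter-sample chimera and is rejected
outright — that is the point of the dual-tag design.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Iterator

SHEET_COLUMNS = (
    "sample_id", "marker", "tag", "fwd_primer", "rev_primer",
    "site", "community", "fraction", "replicate", "is_control",
)


class SampleSheetError(ValueError):
    pass


@dataclass(frozen=True)
class SampleSheetEntry:
    sample_id: str
    marker: str
    tag: str
    fwd_primer: str
    rev_primer: str
    site: str = ""
    community: str = ""
    fraction: str = ""
    replicate: str = ""
    is_control: bool = False

    def __post_init__(self):
        if len(self.tag) != 8:
            raise SampleSheetError(
                f"tag for {self.sample_id!r} must be 8 nt, got {self.tag!r}")
        if set(self.tag.upper()) - set("ACGT"):
            raise SampleSheetError(f"tag {self.tag!r} has non-ACGT characters")
        if not self.is_control and self.fraction not in ("", "A", "B", "C"):
            raise SampleSheetError(
                f"fraction must be A/B/C for non-controls, got {self.fraction!r}")


class SampleSheet:
    """Collection of entries with per-marker tag uniqueness enforced."""

    def __init__(self, entries: Iterable[SampleSheetEntry]):
        self.entries: list[SampleSheetEntry] = list(entries)
        seen: dict[tuple[str, str], str] = {}
        ids: set[str] = set()
        for e in self.entries:
            key = (e.marker, e.tag.upper())
            if key in seen:
                raise SampleSheetError(
                    f"tag collision: {e.tag} used by both {seen[key]!r} "
                    f"and {e.sample_id!r} for marker {e.marker}")
            seen[key] = e.sample_id
            if e.sample_id in ids:
                raise SampleSheetError(f"duplicate sample_id {e.sample_id!r}")
            ids.add(e.sample_id)

    def __iter__(self) -> Iterator[SampleSheetEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def for_marker(self, marker: str) -> list[SampleSheetEntry]:
        return [e for e in self.entries if e.marker == marker]

    def tag_map(self, marker: str) -> dict[str, str]:
        """tag -> sample_id for one marker."""
        return {e.tag.upper(): e.sample_id for e in self.for_marker(marker)}

    def entry(self, sample_id: str) -> SampleSheetEntry:
        for e in self.entries:
            if e.sample_id == sample_id:
                return e
        raise SampleSheetError(f"unknown sample_id {sample_id!r}")

    def control_ids(self, marker: str | None = None) -> list[str]:
        return [e.sample_id for e in self.entries
                if e.is_control and (marker is None or e.marker == marker)]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=SHEET_COLUMNS, delimiter="\t")
            w.writeheader()
            for e in self.entries:
                row = asdict(e)
                row["is_control"] = "1" if e.is_control else "0"
                w.writerow(row)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleSheet":
        entries = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                row["is_control"] = row.get("is_control", "0") in ("1", "true", "True")
                entries.append(SampleSheetEntry(**{
                    k: row[k] for k in SHEET_COLUMNS if k in row}))
        return cls(entries)
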