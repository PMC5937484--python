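"""Pairwise identity used by clustering and taxonomic assignment.

One metric is used consistently across the pipeline: number of matching
columns divided by the total number of columns of a global (Needleman-Wunsch)
alignment, with indel columns counting as mismatches.  Alignments come from
edlib (unit-cost edit distance with traceback).
"""

from __future__ import annotations

import re

import edlib

_CIG = re.compile(r"(\d+)([=XIDM])")


def global_identity(a: str, b: str) -> float:
    """Global-alignment identity of two sequences in [0, 1].

    identity = matching columns / alignment length; insertions and deletions
    count as non-matching columns.  Empty-vs-empty is defined as 1.0,
    empty-vs-nonempty as 0.0.
    """
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    matches = 0
    length = 0
    for n, op in _CIG.findall(res["cigar"]):
        n = int(n)
        length += n
        if op == "=":
            matches += n
    return matches / length


def edit_distance(a: str, b: str) -> int:
    """Unit-cost global edit distance."""
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]
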