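"""Low-level sequence utilities: complements, IUPAC degeneracy, bit encodings.

IUPAC degeneracy codes map a single letter to a set of plain bases.  Inosine
("I"), a base analogue used in highly degenerate primers, pairs with any
template base and is treated like N.  Internally each plain base is one bit
(A=1, C=2, G=4, T=8) so that "window base is allowed by primer code" is a
single bitwise AND.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNIacgtryswkmbdhvni",
                            "TGCAYRSWMKVHDBNItgcayrswmkvhdbni")

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "I": frozenset("ACGT"),  # inosine pairs with every base
}

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}

# 256-entry lookup tables keyed by ASCII byte value
BASE_BITS = np.zeros(256, dtype=np.uint8)
CODE_MASK = np.zeros(256, dtype=np.uint8)
for _code, _bases in IUPAC_SETS.items():
    _mask = 0
    for _b in _bases:
        _mask |= _BASE_BIT[_b]
    CODE_MASK[ord(_code)] = _mask
    CODE_MASK[ord(_code.lower())] = _mask
for _b, _bit in _BASE_BIT.items():
    BASE_BITS[ord(_b)] = _bit
    BASE_BITS[ord(_b.lower())] = _bit
# N in a read is ambiguous: it can never be trusted to match a primer base
BASE_BITS[ord("N")] = 0
BASE_BITS[ord("n")] = 0

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_bytes(seq: str) -> np.ndarray:
    """ASCII byte view of a sequence (uint8 array)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def code_matches(code: str, base: str) -> bool:
    """True if ``base`` is in the degeneracy set of primer letter ``code``."""
    try:
        allowed = IUPAC_SETS[code.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC/inosine code: {code!r}") from None
    return base.upper() in allowed


def is_superset_code(code_sub: str, code_sup: str) -> bool:
    """True if the base set of ``code_sup`` contains that of ``code_sub``."""
    return IUPAC_SETS[code_sub.upper()] <= IUPAC_SETS[code_sup.upper()]


@lru_cache(maxsize=64)
def primer_mask(primer: str) -> np.ndarray:
    """Bit-mask array for a primer string; raises on invalid letters.

    Cached per primer; treat the returned array as read-only.
    """
    arr = seq_to_bytes(primer)
    mask = CODE_MASK[arr]
    if (mask == 0).any():
        bad = primer[int(np.argmax(mask == 0))]
        raise ValueError(f"invalid primer code: {bad!r}")
    mask.flags.writeable = False
    return mask


def count_mismatches(primer: str, window: str) -> int:
    """Ungapped mismatch count of a primer against an equal-length window.

    A position matches when the window base belongs to the primer code's base
    set; I and N in the primer match everything, N in the window matches
    nothing.
    """
    if len(primer) != len(window):
        raise ValueError(
            f"primer length {len(primer)} != window length {len(window)}"
        )
    pm = primer_mask(primer)
    wb = BASE_BITS[seq_to_bytes(window)]
    return int(np.count_nonzero((pm & wb) == 0))


def phred_to_ascii(quals) -> str:
    """Phred scores -> Sanger (Phred+33) quality string."""
    return "".join(chr(int(q) + 33) for q in quals)


def ascii_to_phred(qstr: str) -> np.ndarray:
    """Sanger quality string -> int array of Phred scores."""
    return seq_to_bytes(qstr).astype(np.int64) - 33
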