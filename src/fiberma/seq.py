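"""Small sequence helpers shared across the pipeline.

All sequences are stored internally in the DNA alphabet (T, not U); report
renderers may transliterate to RNA for display.  Coordinates are 0-based,
half-open on the internal side; 1-based closed in GFF3 and reports.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

from .errors import AlphabetError

DNA_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement in the DNA alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.replace("T", "U").replace("t", "u")


def to_dna(seq: str) -> str:
    return seq.replace("U", "T").replace("u", "t")


def check_alphabet(seq: str, *, allow_n: bool = False) -> str:
    """Return ``seq`` upper-cased and T-normalised, or raise AlphabetError."""
    s = to_dna(seq.upper())
    allowed = DNA_ALPHABET | ({"N"} if allow_n else set())
    bad = set(s) - allowed
    if bad:
        raise AlphabetError(f"non-nucleotide characters {sorted(bad)!r} in sequence")
    return s


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def gc_percent(seq: str) -> float:
    """G+C content as a percentage (0-100)."""
    if not seq:
        return 0.0
    gc = sum(1 for c in seq if c in "GCgc")
    return 100.0 * gc / len(seq)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (report convention; avoids banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: float, total: float, ndigits: int = 2) -> float:
    """count/total as a percentage, half-up rounded (Table-style reporting)."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, ndigits)
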