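"""Assignment of reads to known mature miRNAs (miRBase-style reference).

A read is assigned to the reference mature with the fewest substitutions,
up to two, at equal length; ties split the read's count equally across the
tied references.  Length variants (up to 2 nt at the 3' end) are recorded as
isomiR variants of the same call rather than separate miRNAs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .annotate import AnnotatedLibrary
from .errors import EmptyInputError, ReferenceFormatError
from .seq import hamming

_FAMILY_RE = re.compile(r"(miR(?:na)?[A-Za-z]?\d+)", re.IGNORECASE)


def parse_family(mirna_id: str) -> str:
    """Family token from a miRBase-style ID, e.g. 'gar-miR156a' -> 'miR156'."""
    m = _FAMILY_RE.search(mirna_id)
    if not m:
        return mirna_id
    return m.group(1)


@dataclass
class Variant:
    sequence: str
    mismatches: int
    length_variant: bool
    counts: dict[str, float] = field(default_factory=dict)  # library -> count


@dataclass
class KnownMiRNACall:
    mirna_id: str
    family: str
    canonical_sequence: str
    variants: dict[str, Variant] = field(default_factory=dict)

    def totals(self, labels: list[str]) -> dict[str, float]:
        out = {lab: 0.0 for lab in labels}
        for v in self.variants.values():
            for lab, n in v.counts.items():
                out[lab] = out.get(lab, 0.0) + n
        return out


def load_mature_reference(records: list[tuple[str, str]]) -> dict[str, str]:
    """Validate (id, mature) records; duplicate IDs are a format error."""
    if not records:
        raise EmptyInputError("mature reference is empty")
    ref: dict[str, str] = {}
    for rid, seq in records:
        if rid in ref:
            raise ReferenceFormatError(f"duplicate reference ID {rid!r}")
        ref[rid] = seq.upper().replace("U", "T")
    return ref


def _match_candidates(seq: str, by_len: dict[int, list[tuple[str, str]]],
                      max_mismatch: int) -> tuple[list[str], int, bool]:
    """Best-matching reference IDs for a read, (ids, mismatches, length_variant)."""
    L = len(seq)
    # exact-length substitution matching is decisive
    best: list[str] = []
    best_d = max_mismatch + 1
    for rid, ref in by_len.get(L, ()):
        d = hamming(seq, ref)
        if d < best_d:
            best, best_d = [rid], d
        elif d == best_d:
            best.append(rid)
    if best:
        return best, best_d, False
    # 3'-length isomiRs: 5' ends aligned, length differs by <= 2
    for delta in (1, -1, 2, -2):
        for rid, ref in by_len.get(L - delta, ()):
            ov = min(L, len(ref))
            d = hamming(seq[:ov], ref[:ov])
            if d < best_d:
                best, best_d = [rid], d
            elif d == best_d and best:
                best.append(rid)
        if best:
            return best, best_d, True
    return [], -1, False


def assign_known(
    libs: list[AnnotatedLibrary],
    mature_ref: dict[str, str] | list[tuple[str, str]],
    max_mismatch: int = 2,
) -> tuple[list[KnownMiRNACall], set[str]]:
    """Assign reads across all libraries to known matures.

    Returns the calls (one per reference with any support) and the set of
    assigned read sequences (to be excluded from novel prediction).
    Contaminant-classed reads are never assigned.
    """
    if not isinstance(mature_ref, dict):
        mature_ref = load_mature_reference(mature_ref)
    else:
        load_mature_reference(list(mature_ref.items()))
    by_len: dict[int, list[tuple[str, str]]] = {}
    for rid, ref in mature_ref.items():
        by_len.setdefault(len(ref), []).append((rid, ref))

    calls: dict[str, KnownMiRNACall] = {}
    assigned: set[str] = set()
    cache: dict[str, tuple[list[str], int, bool]] = {}
    for al in libs:
        label = al.label
        for seq, n in al.library.unique_reads.items():
            ann = al.annotations.get(seq)
            if ann is not None and ann.annotation_class != "none":
                continue
            if seq not in cache:
                cache[seq] = _match_candidates(seq, by_len, max_mismatch)
            ids, d, lenvar = cache[seq]
            if not ids:
                continue
            assigned.add(seq)
            share = n / len(ids)  # tie -> equal split keeps totals conserved
            for rid in ids:
                call = calls.setdefault(
                    rid,
                    KnownMiRNACall(rid, parse_family(rid), mature_ref[rid]),
                )
                var = call.variants.setdefault(seq, Variant(seq, d, lenvar))
                var.counts[label] = var.counts.get(label, 0.0) + share
    ordered = [calls[k] for k in sorted(calls)]
    return ordered, assigned


def family_summary(calls: list[KnownMiRNACall]) -> pd.DataFrame:
    """Family -> member count; members are distinct canonical sequences/loci."""
    rows: dict[str, set[str]] = {}
    for c in calls:
        rows.setdefault(c.family, set()).add(c.mirna_id)
    return pd.DataFrame(
        {"family": sorted(rows), "members": [len(rows[f]) for f in sorted(rows)]}
    )


def calls_to_frame(calls: list[KnownMiRNACall], labels: list[str]) -> pd.DataFrame:
    rows = []
    for c in calls:
        tot = c.totals(labels)
        rows.append(
            {"mirna_id": c.mirna_id, "family": c.family,
             "canonical_sequence": c.canonical_sequence,
             "n_variants": len(c.variants),
             **{lab: tot[lab] for lab in labels}}
        )
    return pd.DataFrame(rows)
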