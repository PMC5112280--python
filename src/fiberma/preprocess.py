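"""Raw FASTQ to collapsed, length-filtered clean-read libraries.

Cleaning locates and trims the 3' sequencing adaptor, discards low-quality,
N-containing, adaptor-less and out-of-bounds reads, and collapses survivors
to unique sequences with counts.  Two length regimes are supported: a broad
cleaning window (18-44 nt) and the analysis window (18-28 nt) used for miRNA
work; ``ReadLibrary.restrict`` converts one into the other.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .errors import EmptyInputError, FastqParseError
from .seq import check_alphabet

DISCARD_REASONS = ("no_adaptor", "low_quality", "contains_n", "too_short", "too_long")


@dataclass
class ReadLibrary:
    """A collapsed small-RNA library: unique sequences with counts."""

    label: str
    unique_reads: dict[str, int] = field(default_factory=dict)
    discards: Counter = field(default_factory=Counter)

    @property
    def total_clean_reads(self) -> int:
        return sum(self.unique_reads.values())

    @property
    def n_unique(self) -> int:
        return len(self.unique_reads)

    @property
    def length_histogram(self) -> dict[int, int]:
        hist: Counter[int] = Counter()
        for seq, n in self.unique_reads.items():
            hist[len(seq)] += n
        return dict(sorted(hist.items()))

    def restrict(self, min_len: int, max_len: int) -> "ReadLibrary":
        """Analysis-window subset (counts for out-of-window reads dropped)."""
        kept = {s: n for s, n in self.unique_reads.items() if min_len <= len(s) <= max_len}
        return ReadLibrary(label=self.label, unique_reads=kept, discards=Counter(self.discards))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            sorted(self.unique_reads.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["sequence", "count"],
        )
        return df


def find_adaptor(read: str, adaptor: str, min_overlap: int = 8, max_mismatch: int = 1) -> int:
    """Leftmost start of the 3' adaptor in ``read``, or -1.

    The adaptor is matched by its longest prefix fitting the read tail; a
    match needs >= ``min_overlap`` aligned bases and <= ``max_mismatch``
    substitutions.
    """
    n = len(read)
    for p in range(0, n - min_overlap + 1):
        k = min(len(adaptor), n - p)
        if k < min_overlap:
            break
        mism = 0
        for a, b in zip(read[p : p + k], adaptor):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return p
    return -1


def clean_reads(
    fastq,
    adaptor_3p: str,
    *,
    label: str | None = None,
    min_len: int = 18,
    max_len: int = 28,
    min_qual: int = 20,
    min_overlap: int = 8,
    max_adaptor_mismatch: int = 1,
) -> ReadLibrary:
    """Trim the 3' adaptor and collapse surviving reads.

    ``fastq`` may be a path, an open handle, or an iterable of
    ``(read_id, sequence, phred_qualities)`` triples.  Discards are tallied
    by reason in ``ReadLibrary.discards``.
    """
    if not adaptor_3p:
        raise ValueError("adaptor_3p must be non-empty")
    adaptor = adaptor_3p.upper()
    if label is None:
        label = Path(fastq).stem if isinstance(fastq, (str, Path)) else "library"
    lib = ReadLibrary(label=label)
    counts: Counter[str] = Counter()

    def records():
        if isinstance(fastq, (str, Path)) or isinstance(fastq, io.IOBase):
            handle = open(fastq) if isinstance(fastq, (str, Path)) else fastq
            idx = -1
            try:
                for idx, rec in enumerate(SeqIO.parse(handle, "fastq")):
                    yield str(rec.seq), rec.letter_annotations["phred_quality"]
            except ValueError as exc:
                raise FastqParseError(f"malformed FASTQ at record {idx + 1}: {exc}",
                                      record_index=idx + 1) from exc
            finally:
                if isinstance(fastq, (str, Path)):
                    handle.close()
        else:
            for _, seq, quals in fastq:
                yield seq, quals

    for seq, quals in records():
        seq = seq.upper().replace("U", "T")
        p = find_adaptor(seq, adaptor, min_overlap, max_adaptor_mismatch)
        if p < 0:
            lib.discards["no_adaptor"] += 1
            continue
        insert = seq[:p]
        iquals = quals[:p]
        if iquals and min(iquals) < min_qual:
            lib.discards["low_quality"] += 1
            continue
        if "N" in insert:
            lib.discards["contains_n"] += 1
            continue
        if len(insert) < min_len:
            lib.discards["too_short"] += 1
            continue
        if len(insert) > max_len:
            lib.discards["too_long"] += 1
            continue
        check_alphabet(insert)
        counts[insert] += 1

    lib.unique_reads = dict(counts)
    return lib


def length_distribution(lib: ReadLibrary) -> pd.DataFrame:
    """Length -> count and fraction table; fractions sum to 1.

    The aggregate 20-24 nt fraction is stored in ``df.attrs['fraction_20_24']``.
    """
    if lib.total_clean_reads == 0:
        raise EmptyInputError(f"library {lib.label!r} is empty")
    hist = lib.length_histogram
    total = sum(hist.values())
    df = pd.DataFrame(
        {"length": list(hist), "count": list(hist.values())}
    )
    df["fraction"] = df["count"] / total
    df.attrs["fraction_20_24"] = float(
        df.loc[df["length"].between(20, 24), "count"].sum() / total
    )
    return df


def fraction_in_range(lib: ReadLibrary, lo: int = 20, hi: int = 24) -> float:
    total = lib.total_clean_reads
    if total == 0:
        raise EmptyInputError(f"library {lib.label!r} is empty")
    n = sum(c for s, c in lib.unique_reads.items() if lo <= len(s) <= hi)
    return n / total
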