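"""Read-class annotation and genome matching.

Assigns each unique read to one class (rRNA/tRNA/snRNA/snoRNA/repeat by
reference-subsequence matching, else genome-matched, else no annotation) and
records every genomic occurrence up to a mismatch budget.  The genome mapper
is a k-mer seed-and-extend scanner whose contract is exact hit-set equality
with a brute-force all-positions oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError
from .preprocess import ReadLibrary
from .seq import percent, revcomp

DEFAULT_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat")


@dataclass(frozen=True)
class GenomeHit:
    """One genomic occurrence; 0-based half-open interval on the + strand."""

    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int


@dataclass
class ReadAnnotation:
    annotation_class: str = "none"  # rRNA/tRNA/snRNA/snoRNA/repeat/none
    genome_hits: list[GenomeHit] = field(default_factory=list)
    multimapper: bool = False


@dataclass
class AnnotatedLibrary:
    """A ReadLibrary plus per-sequence class and genome-hit annotations."""

    library: ReadLibrary
    annotations: dict[str, ReadAnnotation] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return self.library.label

    def annotation(self, seq: str) -> ReadAnnotation:
        return self.annotations.setdefault(seq, ReadAnnotation())

    def class_counts(self, weighted: bool = True) -> dict[str, int]:
        """Reads per class; genome-matched non-contaminants under 'genome'."""
        out: dict[str, int] = {c: 0 for c in (*DEFAULT_PRIORITY, "genome", "none")}
        for seq, n in self.library.unique_reads.items():
            ann = self.annotations.get(seq, ReadAnnotation())
            w = n if weighted else 1
            if ann.annotation_class != "none":
                out[ann.annotation_class] += w
            elif ann.genome_hits:
                out["genome"] += w
            else:
                out["none"] += w
        return out


class GenomeIndex:
    """k-mer seed-and-extend index for exhaustive short-read matching.

    Finds *all* occurrences of a read on both strands with at most
    ``max_mismatch`` substitutions (no indels).  Minus-strand hits are found
    by searching the reverse complement on the forward text and are reported
    on forward-strand half-open coordinates.  Pigeonhole seeding guarantees
    completeness: a read split into ``max_mismatch + 1`` disjoint k-mers must
    have one exact seed in any qualifying alignment.
    """

    def __init__(self, genome: dict[str, str] | str, max_mismatch: int = 0,
                 min_read_len: int = 18):
        if isinstance(genome, str):
            genome = {"chr1": genome}
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.max_mismatch = max_mismatch
        self.k = max(4, min_read_len // (max_mismatch + 1))
        self._index: dict[str, dict[str, list[int]]] = {}
        for chrom, seq in self.genome.items():
            idx: dict[str, list[int]] = {}
            k = self.k
            for i in range(len(seq) - k + 1):
                idx.setdefault(seq[i : i + k], []).append(i)
            self._index[chrom] = idx

    def _find_forward(self, chrom: str, query: str) -> list[tuple[int, int]]:
        """All (start, mismatches) of query on the forward text of chrom."""
        seq = self.genome[chrom]
        idx = self._index[chrom]
        k, mm = self.k, self.max_mismatch
        L = len(query)
        if L < k:
            return []  # shorter than the seed: not supported (reads >= 18 nt)
        n_seeds = mm + 1
        candidates: set[int] = set()
        for j in range(n_seeds):
            off = j * k
            if off + k > L:
                break
            for pos in idx.get(query[off : off + k], ()):
                s = pos - off
                if 0 <= s <= len(seq) - L:
                    candidates.add(s)
        hits = []
        for s in sorted(candidates):
            d = 0
            window = seq[s : s + L]
            for a, b in zip(window, query):
                if a != b:
                    d += 1
                    if d > mm:
                        break
            else:
                hits.append((s, d))
        return hits

    def find(self, read: str) -> list[GenomeHit]:
        """All hits on both strands, sorted by (chrom, start, strand)."""
        read = read.upper()
        out: list[GenomeHit] = []
        rc = revcomp(read)
        for chrom in self.genome:
            for s, d in self._find_forward(chrom, read):
                out.append(GenomeHit(chrom, s, s + len(read), "+", d))
            for s, d in self._find_forward(chrom, rc):
                out.append(GenomeHit(chrom, s, s + len(read), "-", d))
        out.sort(key=lambda h: (h.chrom, h.start, h.strand))
        return out


def brute_force_hits(genome: dict[str, str] | str, read: str,
                     max_mismatch: int = 0) -> list[GenomeHit]:
    """Quadratic-time all-positions oracle for the genome mapper."""
    if isinstance(genome, str):
        genome = {"chr1": genome}
    read = read.upper()
    out: list[GenomeHit] = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        for query, strand in ((read, "+"), (revcomp(read), "-")):
            L = len(query)
            for s in range(len(seq) - L + 1):
                d = sum(1 for a, b in zip(seq[s : s + L], query) if a != b)
                if d <= max_mismatch:
                    out.append(GenomeHit(chrom, s, s + L, strand, d))
    out.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return out


def classify_contaminants(
    lib: ReadLibrary | AnnotatedLibrary,
    refs_by_class: dict[str, list[tuple[str, str]]],
    max_mismatch: int = 0,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> AnnotatedLibrary:
    """Label reads with the first reference class containing them.

    A read belongs to a class when it occurs as a subsequence of any of that
    class's reference sequences with at most ``max_mismatch`` substitutions.
    Classes are tried in ``priority`` order; unmatched reads stay 'none'.
    """
    ann = lib if isinstance(lib, AnnotatedLibrary) else AnnotatedLibrary(library=lib)
    for cls in refs_by_class:
        if not refs_by_class[cls]:
            raise ConfigurationError(f"empty reference set for class {cls!r}")
    ordered = [c for c in priority if c in refs_by_class]
    # concatenated per-class text with separators for fast exact search
    texts = {cls: "#".join(seq.upper() for _, seq in refs_by_class[cls]) for cls in ordered}
    for seq in ann.library.unique_reads:
        a = ann.annotation(seq)
        for cls in ordered:
            if max_mismatch == 0:
                found = seq in texts[cls]
            else:
                found = any(
                    _approx_substring(seq, ref.upper(), max_mismatch)
                    for _, ref in refs_by_class[cls]
                )
            if found:
                a.annotation_class = cls
                break
    return ann


def _approx_substring(read: str, text: str, max_mismatch: int) -> bool:
    L = len(read)
    for s in range(len(text) - L + 1):
        d = 0
        for a, b in zip(text[s : s + L], read):
            if a != b:
                d += 1
                if d > max_mismatch:
                    break
        else:
            return True
    return False


def map_to_genome(
    lib: ReadLibrary | AnnotatedLibrary,
    genome: dict[str, str] | str | GenomeIndex,
    max_mismatch: int = 0,
    max_hits: int = 20,
) -> AnnotatedLibrary:
    """Record all genomic occurrences of every unique read.

    Reads with more than ``max_hits`` occurrences are flagged multi-mapper
    (still genome-matched, but excluded from novel-locus seeding).
    """
    ann = lib if isinstance(lib, AnnotatedLibrary) else AnnotatedLibrary(library=lib)
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome, max_mismatch)
    for seq in ann.library.unique_reads:
        a = ann.annotation(seq)
        hits = index.find(seq)
        a.genome_hits = hits
        a.multimapper = len(hits) > max_hits
    return ann


TABLE1_ROWS = ("Clean reads", "Match to genome", "rRNA", "tRNA",
               "snRNA", "snoRNA", "Repeats", "No annotation")
_ROW_TO_CLASS = {"Match to genome": "genome", "rRNA": "rRNA", "tRNA": "tRNA",
                 "snRNA": "snRNA", "snoRNA": "snoRNA", "Repeats": "repeat",
                 "No annotation": "none"}


def class_distribution_from_counts(
    counts_by_lib: dict[str, dict[str, int]],
    clean_by_lib: dict[str, int],
) -> pd.DataFrame:
    """Read-class distribution table from raw class counts.

    Percents are count/clean_reads x 100, two decimals, half-up; clean reads
    are shown as 100%.  Input classes: genome, rRNA, tRNA, snRNA, snoRNA,
    repeat, none.
    """
    cols: dict[str, list] = {"RNA class": list(TABLE1_ROWS)}
    for lib, cc in counts_by_lib.items():
        clean = clean_by_lib[lib]
        col_n, col_p = [], []
        for row in TABLE1_ROWS:
            if row == "Clean reads":
                n = clean
            else:
                n = cc.get(_ROW_TO_CLASS[row], 0)
            col_n.append(n)
            col_p.append(percent(n, clean))
        cols[f"{lib} count"] = col_n
        cols[f"{lib} percent"] = col_p
    return pd.DataFrame(cols)


def class_distribution_table(libs: list[AnnotatedLibrary]) -> pd.DataFrame:
    """Per-library read-class distribution (count and percent columns)."""
    counts = {al.label: al.class_counts() for al in libs}
    clean = {al.label: al.library.total_clean_reads for al in libs}
    return class_distribution_from_counts(counts, clean)
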