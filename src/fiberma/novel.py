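"""Novel miRNA prediction from mapped read stacks.

Candidate loci are seeded from clusters of uniquely-placed, unannotated
reads; for each cluster's modal read two flanking windows are folded (the
mature may sit on either hairpin arm) and the hairpin is judged against the
plant-miRNA annotation criteria: the mature must lie in one arm with few
unpaired bases, the mature/star duplex may carry only limited mismatches and
at most two asymmetric bulges, mature+star reads must dominate the locus,
and the fold must be stable (MFE ceiling).  The minimal folding free energy
index MFEI = 100*|MFE| / (length * GC%) is recorded for every candidate and
flagged at 0.85, but is not a hard filter.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .annotate import AnnotatedLibrary
from .errors import CoordinateError
from .folding import Folder, default_folder, pair_table
from .seq import gc_percent, revcomp, round_half_up, to_rna


@dataclass
class HairpinThresholds:
    max_unpaired_mature: int = 4
    max_duplex_mismatches: int = 4
    max_asymmetric_bulges: int = 2
    min_dominance: float = 0.8
    max_mfe: float = -18.0  # kcal/mol
    mfei_flag: float = 0.85


@dataclass
class ClusterRead:
    seq: str
    start: int  # genome coords, 0-based half-open
    end: int
    counts: dict[str, int]  # per-library

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class CandidateWindow:
    chrom: str
    strand: str
    start: int  # window interval on the genome
    end: int
    mature_seq: str
    mature_start: int  # genome coords of the modal (prospective mature) read
    mature_end: int
    reads: list[ClusterRead] = field(default_factory=list)


@dataclass
class HairpinCandidate:
    """A folded candidate precursor with all criteria evaluated."""

    chrom: str
    start: int
    end: int
    strand: str
    precursor_seq: str
    structure: str
    mfe: float
    length: int
    gc_percent: float
    mfei: float
    mfei_flag: bool
    mature_seq: str
    mature_arm: str  # 5p / 3p / none
    star_seq: str
    star_start: int  # genome coords (0 span when undetermined)
    star_end: int
    duplex_mismatches: int
    asymmetric_bulges: int
    unpaired_mature: int
    dominance: float
    read_support: dict[str, int]
    failed: list[str]

    @property
    def verdict(self) -> str:
        return "pass" if not self.failed else "fail"


def compute_mfei(mfe: float, length: int, gc_pct: float) -> float:
    """MFEI = 100*|MFE| / (length * GC%), GC as a percentage (e.g. 50)."""
    if length == 0 or gc_pct == 0:
        return 0.0
    return 100.0 * abs(mfe) / (length * gc_pct)


def seed_loci(
    libs: list[AnnotatedLibrary],
    assigned_known: set[str] | None = None,
    min_stack: int = 5,
    window: int = 250,
    merge_gap: int = 10,
) -> list[CandidateWindow]:
    """Cluster unannotated read placements and emit folding windows.

    For each cluster whose summed read count reaches ``min_stack``, the modal
    read is taken as the prospective mature and two windows are emitted:
    ``[mature_start - window, mature_end + 20)`` and
    ``[mature_start - 20, mature_end + window)``, so the mature can sit on
    either hairpin arm.
    """
    assigned_known = assigned_known or set()
    placements: dict[tuple[str, str], list[tuple[int, int, str]]] = defaultdict(list)
    counts: dict[str, dict[str, int]] = defaultdict(dict)
    for al in libs:
        for seq, n in al.library.unique_reads.items():
            ann = al.annotations.get(seq)
            if ann is None or not ann.genome_hits or ann.multimapper:
                continue
            if ann.annotation_class != "none" or seq in assigned_known:
                continue
            counts[seq][al.label] = counts[seq].get(al.label, 0) + n
    for seq in counts:
        # placements are a property of the sequence; take them from the
        # first library that saw the read
        for al in libs:
            ann = al.annotations.get(seq)
            if ann is not None and ann.genome_hits:
                for h in ann.genome_hits:
                    placements[(h.chrom, h.strand)].append((h.start, h.end, seq))
                break

    out: list[CandidateWindow] = []
    for (chrom, strand), items in sorted(placements.items()):
        items.sort()
        cluster: list[tuple[int, int, str]] = []
        cur_end = None
        for start, end, seq in items + [(1 << 60, 1 << 60, "")]:
            if cur_end is not None and start - cur_end > merge_gap:
                out.extend(
                    _emit_windows(chrom, strand, cluster, counts, min_stack, window)
                )
                cluster = []
                cur_end = None
            if seq:
                cluster.append((start, end, seq))
                cur_end = end if cur_end is None else max(cur_end, end)
    return out


def _emit_windows(chrom, strand, cluster, counts, min_stack, window):
    if not cluster:
        return []
    reads = [
        ClusterRead(seq, s, e, dict(counts[seq])) for s, e, seq in cluster
    ]
    total = sum(r.total for r in reads)
    if total < min_stack:
        return []
    modal = max(reads, key=lambda r: (r.total, -r.start, r.seq))
    wins = []
    for ws, we in (
        (modal.start - window, modal.end + 20),
        (modal.start - 20, modal.end + window),
    ):
        wins.append(
            CandidateWindow(
                chrom=chrom, strand=strand, start=max(0, ws), end=we,
                mature_seq=modal.seq, mature_start=modal.start,
                mature_end=modal.end, reads=reads,
            )
        )
    return wins


def _duplex_walk(pt: list[int], a: int, b: int) -> tuple[int, int, int]:
    """Walk the mature/star duplex; return (mismatches, asym_bulges, unpaired).

    ``[a, b)`` is the mature interval on the precursor.  Between consecutive
    paired mature bases, positions opposite each other on both strands count
    as mismatches (min of the two unpaired runs); runs of unequal size count
    one asymmetric bulge each.
    """
    anchors = [i for i in range(a, b) if pt[i] >= 0]
    unpaired = (b - a) - len(anchors)
    mism = 0
    bulges = 0
    for i1, i2 in zip(anchors, anchors[1:]):
        u_m = i2 - i1 - 1
        u_s = abs(pt[i1] - pt[i2]) - 1
        mism += min(u_m, u_s)
        if u_m != u_s:
            bulges += 1
    return mism, bulges, unpaired


def evaluate_hairpin(
    win: CandidateWindow,
    genome: dict[str, str],
    folder: Folder | None = None,
    thresholds: HairpinThresholds | None = None,
) -> HairpinCandidate:
    """Fold a candidate window and evaluate every annotation criterion."""
    th = thresholds or HairpinThresholds()
    folder = folder or default_folder()
    chrom_seq = genome[win.chrom]
    if not (0 <= win.start < win.end <= len(chrom_seq)):
        win = CandidateWindow(**{**win.__dict__, "end": min(win.end, len(chrom_seq))})
    pre = chrom_seq[win.start : win.end].upper()
    if win.strand == "-":
        pre = revcomp(pre)
    # mature offset within the folded (strand-oriented) precursor
    if win.strand == "+":
        a = win.mature_start - win.start
    else:
        a = win.end - win.mature_end
    b = a + (win.mature_end - win.mature_start)
    if not (0 <= a < b <= len(pre)):
        raise CoordinateError("mature read not contained in the candidate window")

    structure, mfe = folder.fold(pre)
    pt = pair_table(structure)
    gc = gc_percent(pre)
    mfei = compute_mfei(mfe, len(pre), gc)

    failed: list[str] = []
    anchors = [i for i in range(a, b) if pt[i] >= 0]
    in_arm = bool(anchors) and not any(a <= pt[i] < b for i in anchors)
    mism, bulges, unpaired = _duplex_walk(pt, a, b) if in_arm else (0, 0, b - a)
    if in_arm:
        # canonical Dicer duplexes carry 2-nt 3' overhangs: up to two
        # unpaired bases at each mature terminus are outside the duplex
        # and do not count against the unpaired-mature budget
        leading = anchors[0] - a
        trailing = (b - 1) - anchors[-1]
        unpaired -= min(leading, 2) + min(trailing, 2)
    if not in_arm or unpaired > th.max_unpaired_mature:
        failed.append("mature_in_arm")
    if in_arm and mism > th.max_duplex_mismatches:
        failed.append("duplex_mismatches")
    if in_arm and bulges > th.max_asymmetric_bulges:
        failed.append("asymmetric_bulges")
    if mfe > th.max_mfe:
        failed.append("mfe")

    # star from the pair table, canonical 2-nt 3' overhang convention
    star_seq, star_iv = "", (0, 0)
    arm = "none"
    if in_arm:
        p_first, p_last = pt[anchors[0]], pt[anchors[-1]]
        lo, hi = min(p_first, p_last), max(p_first, p_last)
        s0, s1 = lo, min(hi + 1 + 2, len(pre))
        star_seq = pre[s0:s1]
        arm = "5p" if a < lo else "3p"
        star_iv = (s0, s1)

    # dominance: mature/star +/- 2 nt reads over all window-overlapping reads
    total = 0
    inside = 0
    star_g = _to_genome_interval(win, star_iv) if star_seq else None
    for r in win.reads:
        if r.end <= win.start or r.start >= win.end:
            continue
        total += r.total
        if _within(r, win.mature_start, win.mature_end, slop=2):
            inside += r.total
        elif star_g and _within(r, star_g[0], star_g[1], slop=2):
            inside += r.total
    dominance = inside / total if total else 0.0
    if dominance < th.min_dominance:
        failed.append("dominance")

    return HairpinCandidate(
        chrom=win.chrom, start=win.start, end=win.end, strand=win.strand,
        precursor_seq=pre, structure=structure, mfe=mfe, length=len(pre),
        gc_percent=gc, mfei=mfei, mfei_flag=mfei >= th.mfei_flag,
        mature_seq=win.mature_seq, mature_arm=arm, star_seq=star_seq,
        star_start=star_g[0] if star_g else 0, star_end=star_g[1] if star_g else 0,
        duplex_mismatches=mism, asymmetric_bulges=bulges,
        unpaired_mature=unpaired, dominance=dominance,
        read_support=_mature_support(win), failed=failed,
    )


def _within(r: ClusterRead, start: int, end: int, slop: int) -> bool:
    return r.start >= start - slop and r.end <= end + slop


def _to_genome_interval(win: CandidateWindow, iv: tuple[int, int]) -> tuple[int, int]:
    if win.strand == "+":
        return win.start + iv[0], win.start + iv[1]
    return win.end - iv[1], win.end - iv[0]


def _mature_support(win: CandidateWindow) -> dict[str, int]:
    support: Counter[str] = Counter()
    for r in win.reads:
        if _within(r, win.mature_start, win.mature_end, slop=2):
            support.update(r.counts)
    return dict(support)


def call_novel(
    libs: list[AnnotatedLibrary],
    genome: dict[str, str],
    assigned_known: set[str] | None = None,
    folder: Folder | None = None,
    thresholds: HairpinThresholds | None = None,
    min_stack: int = 5,
    window: int = 250,
) -> tuple[list[HairpinCandidate], list[HairpinCandidate]]:
    """Seed, fold and evaluate; returns (all candidates, passing calls).

    A locus passing from both emitted windows is deduplicated keeping the
    lower-MFE precursor.
    """
    folder = folder or default_folder()
    wins = seed_loci(libs, assigned_known, min_stack=min_stack, window=window)
    evaluated = [evaluate_hairpin(w, genome, folder, thresholds) for w in wins]
    best: dict[tuple, HairpinCandidate] = {}
    for cand, win in zip(evaluated, wins):
        if cand.failed:
            continue
        key = (cand.chrom, cand.strand, win.mature_start, win.mature_end)
        if key not in best or cand.mfe < best[key].mfe:
            best[key] = cand
    passing = [best[k] for k in sorted(best)]
    return evaluated, passing


def novel_summary(mature_seqs: list[str]) -> pd.DataFrame:
    """5'-nucleotide x length cross-tabulation with totals (RNA alphabet).

    Rows A/U/C/G plus a Total row; columns one per observed length plus a
    Total column and a 'pct' column giving each 5' nucleotide's share of all
    calls to one decimal.
    """
    rows = ["A", "U", "C", "G"]
    lengths = sorted({len(s) for s in mature_seqs})
    tab = pd.DataFrame(0, index=rows + ["Total"], columns=lengths + ["Total"])
    for s in mature_seqs:
        nt = to_rna(s[0].upper())
        tab.loc[nt, len(s)] += 1
        tab.loc[nt, "Total"] += 1
        tab.loc["Total", len(s)] += 1
        tab.loc["Total", "Total"] += 1
    n = len(mature_seqs)
    tab["pct"] = [
        round_half_up(100.0 * tab.loc[r, "Total"] / n, 1) if n and r != "Total" else
        (100.0 if r == "Total" and n else 0.0)
        for r in tab.index
    ]
    tab.index.name = "five_prime_nt"
    return tab


def candidates_to_frame(cands: list[HairpinCandidate]) -> pd.DataFrame:
    rows = []
    for c in cands:
        rows.append(
            {"chrom": c.chrom, "start": c.start, "end": c.end, "strand": c.strand,
             "mature": to_rna(c.mature_seq), "arm": c.mature_arm,
             "length": c.length, "mfe": c.mfe, "gc_percent": round(c.gc_percent, 2),
             "mfei": round_half_up(c.mfei, 2), "mfei_flag": c.mfei_flag,
             "duplex_mismatches": c.duplex_mismatches,
             "asymmetric_bulges": c.asymmetric_bulges,
             "unpaired_mature": c.unpaired_mature,
             "dominance": round(c.dominance, 3),
             "verdict": c.verdict, "failed": ";".join(c.failed)}
        )
    return pd.DataFrame(rows)
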