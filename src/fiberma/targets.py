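"""miRNA target prediction by position-weighted complementarity scoring.

The scheme follows the plant target-prediction convention: per position
(counted from the miRNA 5' end) a penalty of 0 for a Watson-Crick match,
0.5 for a G:U wobble, 1.0 for a mismatch and 2.0 for a gap, with every
penalty doubled inside the seed region (positions 2-13 inclusive).  The
summed penalty is the *expectation*; sites at or below the cutoff
(default 3.0) are reported.  Alignment is antiparallel: miRNA position 1
pairs the 3'-most base of the site on the transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlphabetError
from .seq import check_alphabet, round_half_up

_NT = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class ScoringScheme:
    match: float = 0.0
    gu: float = 0.5
    mismatch: float = 1.0
    gap: float = 2.0
    seed_start: int = 2  # 1-based miRNA positions, inclusive
    seed_end: int = 13
    seed_multiplier: float = 2.0

    def weight(self, pos1: int) -> float:
        """Positional multiplier for 1-based miRNA position ``pos1``."""
        return self.seed_multiplier if self.seed_start <= pos1 <= self.seed_end else 1.0

    def pair_penalty(self, mirna_base: str, target_base: str) -> tuple[float, str]:
        """(unweighted penalty, state) for one miRNA:target base pair."""
        if _COMP.get(mirna_base) == target_base:
            return self.match, "match"
        if (mirna_base, target_base) in (("G", "T"), ("T", "G")):
            return self.gu, "GU"
        return self.mismatch, "mismatch"


@dataclass
class TargetHit:
    mirna_id: str
    transcript_id: str
    expectation: float
    start: int  # site interval on the transcript, 0-based half-open
    end: int
    states: list[str] = field(default_factory=list)  # per miRNA position
    aln_mirna: str = ""   # miRNA 5'->3'
    aln_midline: str = ""
    aln_site: str = ""    # target site 3'->5'


def score_duplex(
    mirna_seq: str, site_seq: str, scheme: ScoringScheme | None = None
) -> tuple[float, list[str]]:
    """Expectation and per-position states for an ungapped miRNA:site duplex.

    ``site_seq`` is the transcript subsequence 5'->3'; miRNA position p pairs
    site base ``len(site) - p``.  Sequences must have equal length.
    """
    sch = scheme or ScoringScheme()
    m = check_alphabet(mirna_seq)
    t = check_alphabet(site_seq)
    if not m or not t:
        raise AlphabetError("empty sequence")
    if len(m) != len(t):
        raise ValueError("ungapped duplex scoring requires equal lengths")
    total = 0.0
    states: list[str] = []
    for p, base in enumerate(m, start=1):
        tb = t[len(t) - p]
        pen, state = sch.pair_penalty(base, tb)
        total += pen * sch.weight(p)
        states.append(state)
    return total, states


def _penalty_matrix(mirna: str, transcript: np.ndarray, sch: ScoringScheme) -> np.ndarray:
    """P[p, i] = weighted penalty of miRNA position p against transcript[i]."""
    M = len(mirna)
    table = np.empty((M, 4))
    for p, base in enumerate(mirna):
        for tb, code in _NT.items():
            pen, _ = sch.pair_penalty(base, tb)
            table[p, code] = pen * sch.weight(p + 1)
    return table[:, transcript]  # (M, N)


def _ungapped_scores(P: np.ndarray) -> np.ndarray:
    """S[a] = sum_p P[p, a - p] for every anchor a (miRNA pos 1 pairs a)."""
    M, N = P.shape
    S = np.full(N, np.inf)
    if N < M:
        return S
    acc = np.zeros(N - M + 1)
    for p in range(M):
        # anchor a ranges over [M-1, N); transcript index a-p
        acc += P[p, M - 1 - p : N - p]
    S[M - 1 :] = acc
    return S


def scan_transcripts(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    max_expectation: float = 3.0,
    scheme: ScoringScheme | None = None,
    max_gaps: int = 1,
) -> list[TargetHit]:
    """Score every transcript window against every miRNA; report hits.

    With ``max_gaps = 1`` single-base bulges on either strand are allowed at
    ``scheme.gap`` (seed-weighted); overlapping hits on a transcript keep the
    lowest expectation.  Hits are returned ordered by (miRNA, transcript,
    position).
    """
    sch = scheme or ScoringScheme()
    hits: list[TargetHit] = []
    enc = {
        tid: np.array([_NT[c] for c in check_alphabet(seq)], dtype=np.int64)
        for tid, seq in transcripts.items()
    }
    seqs = {tid: check_alphabet(s) for tid, s in transcripts.items()}
    for mid in sorted(mirnas):
        m = check_alphabet(mirnas[mid])
        M = len(m)
        for tid in sorted(transcripts):
            t = enc[tid]
            N = len(t)
            if N < M:
                continue
            P = _penalty_matrix(m, t, sch)
            variants: list[tuple[np.ndarray, int]] = [(_ungapped_scores(P), 0)]
            if max_gaps >= 1:
                S_t, S_m, _, _ = _one_gap_scores(P, sch)
                variants += [(S_t, -1), (S_m, +1)]
            best: dict[int, tuple[float, int]] = {}
            for S, dlen in variants:
                site_len = M + dlen
                for a in np.flatnonzero(S <= max_expectation):
                    a = int(a)
                    if a - site_len + 1 < 0:
                        continue
                    sc = float(S[a])
                    if a not in best or sc < best[a][0]:
                        best[a] = (sc, site_len)
            # deduplicate overlapping sites: keep lowest expectation, leftmost
            chosen: list[tuple[int, float, int]] = []
            for a in sorted(best, key=lambda x: (best[x][0], x)):
                sc, site_len = best[a]
                s0, s1 = a - site_len + 1, a + 1
                if all(s1 <= cb[0] - cb[2] + 1 or s0 >= cb[0] + 1 for cb in chosen):
                    chosen.append((a, sc, site_len))
            for a, sc, site_len in sorted(chosen):
                s0, s1 = a - site_len + 1, a + 1
                hit = _build_hit(mid, tid, m, seqs[tid], s0, s1, sc, sch)
                hits.append(hit)
    hits.sort(key=lambda h: (h.mirna_id, h.transcript_id, h.start))
    return hits


def _one_gap_scores(P: np.ndarray, sch: ScoringScheme):
    """Best single-gap scores for every anchor.

    Returns (S_tgap, S_mgap, None, None): ``S_tgap[a]`` allows one unpaired
    miRNA base (site one shorter), ``S_mgap[a]`` one unpaired target base
    (site one longer).
    """
    M, N = P.shape
    inf = np.inf
    S_t = np.full(N, inf)
    S_m = np.full(N, inf)
    if N < M + 1 or M < 2:
        return S_t, S_m, None, None
    # prefix[g, a] = sum_{p<g} P[p, a-p]   (frame 0)
    # sufp[g, a]  = sum_{p>=g} P[p, a-p+1] (frame shifted: target gap variant)
    # sufm[g, a]  = sum_{p>=g} P[p, a-p-1] (miRNA gap variant)
    anchors = np.arange(N)
    prefix = np.zeros((M + 1, N))
    for p in range(M):
        idx = anchors - p
        v = np.where((idx >= 0) & (idx < N), P[p, np.clip(idx, 0, N - 1)], inf)
        prefix[p + 1] = prefix[p] + v
    sufp = np.zeros((M + 1, N))
    sufm = np.zeros((M + 1, N))
    for p in range(M - 1, -1, -1):
        ip = anchors - p + 1
        im = anchors - p - 1
        vp = np.where((ip >= 0) & (ip < N), P[p, np.clip(ip, 0, N - 1)], inf)
        vm = np.where((im >= 0) & (im < N), P[p, np.clip(im, 0, N - 1)], inf)
        sufp[p] = sufp[p + 1] + vp
        sufm[p] = sufm[p + 1] + vm
    w = np.array([sch.gap * sch.weight(p + 1) for p in range(M)])
    # target gap at miRNA position g (0-based): miRNA base g unpaired
    cand_t = prefix[:M] + w[:, None] + np.vstack([sufp[g + 1] for g in range(M)])
    S_t = cand_t.min(axis=0)
    # miRNA gap before position g: one extra unpaired target base
    cand_m = np.stack([prefix[g] + sch.gap * sch.weight(min(g + 1, M)) + sufm[g]
                       for g in range(1, M)])
    S_m = cand_m.min(axis=0)
    return S_t, S_m, None, None


def _build_hit(mid, tid, mirna, tseq, s0, s1, expectation, sch) -> TargetHit:
    """Reconstruct the alignment for one site (small local DP, <=1 gap)."""
    site = tseq[s0:s1]
    M, L = len(mirna), len(site)
    states: list[str] = []
    aln_m, aln_mid, aln_s = [], [], []
    site_rev = site[::-1]  # 3'->5' so it runs parallel to the miRNA
    if L == M:
        for p in range(M):
            pen, st = sch.pair_penalty(mirna[p], site_rev[p])
            states.append(st)
            aln_m.append(mirna[p])
            aln_s.append(site_rev[p])
            aln_mid.append({"match": "|", "GU": "o", "mismatch": " "}[st])
    else:
        # locate the gap position that reproduces the expectation
        gap_in_site = L < M
        n_inner = M if gap_in_site else M - 1
        placed = False
        for g in range(n_inner + 1):
            sc = _gapped_alignment_score(mirna, site_rev, g, gap_in_site, sch)
            if sc is not None and abs(sc - expectation) < 1e-9 and not placed:
                placed = True
                _render_gap(mirna, site_rev, g, gap_in_site, sch, states,
                            aln_m, aln_mid, aln_s)
        if not placed:  # fall back: render first feasible gap placement
            _render_gap(mirna, site_rev, 0, gap_in_site, sch, states,
                        aln_m, aln_mid, aln_s)
    return TargetHit(
        mirna_id=mid, transcript_id=tid, expectation=expectation,
        start=s0, end=s1, states=states,
        aln_mirna="".join(aln_m), aln_midline="".join(aln_mid),
        aln_site="".join(aln_s),
    )


def _gapped_alignment_score(mirna, site_rev, g, gap_in_site, sch):
    total = 0.0
    if gap_in_site:  # miRNA base g unpaired
        if g >= len(mirna):
            return None
        si = 0
        for p in range(len(mirna)):
            if p == g:
                total += sch.gap * sch.weight(p + 1)
                continue
            if si >= len(site_rev):
                return None
            pen, _ = sch.pair_penalty(mirna[p], site_rev[si])
            total += pen * sch.weight(p + 1)
            si += 1
        return total if si == len(site_rev) else None
    # extra target base after g miRNA positions
    si = 0
    for p in range(len(mirna)):
        if p == g:
            total += sch.gap * sch.weight(min(p + 1, len(mirna)))
            si += 1
        if si >= len(site_rev):
            return None
        pen, _ = sch.pair_penalty(mirna[p], site_rev[si])
        total += pen * sch.weight(p + 1)
        si += 1
    return total if si == len(site_rev) else None


def _render_gap(mirna, site_rev, g, gap_in_site, sch, states, aln_m, aln_mid, aln_s):
    si = 0
    for p in range(len(mirna)):
        if gap_in_site and p == g:
            states.append("gap")
            aln_m.append(mirna[p])
            aln_mid.append("-")
            aln_s.append("-")
            continue
        if not gap_in_site and p == g:
            states.append("gap")
            aln_m.append("-")
            aln_mid.append("-")
            aln_s.append(site_rev[si])
            si += 1
        if si < len(site_rev):
            pen, st = sch.pair_penalty(mirna[p], site_rev[si])
            states.append(st)
            aln_m.append(mirna[p])
            aln_s.append(site_rev[si])
            aln_mid.append({"match": "|", "GU": "o", "mismatch": " "}[st])
            si += 1


def exhaustive_scan(
    mirna: str, transcript: str, scheme: ScoringScheme | None = None
) -> list[tuple[int, float]]:
    """Gap-free oracle: (site_start, expectation) for every window."""
    sch = scheme or ScoringScheme()
    m = check_alphabet(mirna)
    t = check_alphabet(transcript)
    out = []
    for s in range(len(t) - len(m) + 1):
        e, _ = score_duplex(m, t[s : s + len(m)], sch)
        out.append((s, e))
    return out


def target_summary(hits: list[TargetHit], mirna_ids: list[str]) -> dict:
    """Per-miRNA counts, non-redundant transcript count and mean targets/miRNA.

    The mean is non-redundant (miRNA, transcript) pairs over miRNAs with at
    least one hit, one decimal, half-up.
    """
    pairs = {(h.mirna_id, h.transcript_id) for h in hits}
    per_mirna = pd.Series(
        [sum(1 for p in pairs if p[0] == mid) for mid in mirna_ids], index=mirna_ids
    )
    with_hits = int((per_mirna > 0).sum())
    mean = round_half_up(len(pairs) / with_hits, 1) if with_hits else 0.0
    return {
        "per_mirna": per_mirna,
        "non_redundant_transcripts": len({h.transcript_id for h in hits}),
        "non_redundant_pairs": len(pairs),
        "mirnas_with_hits": with_hits,
        "zero_hit_mirnas": [mid for mid in mirna_ids if per_mirna[mid] == 0],
        "mean_targets_per_mirna": mean,
    }


def mean_targets_per_mirna(n_pairs: int, n_mirnas: int) -> float:
    """Non-redundant pairs per miRNA, one decimal (report arithmetic)."""
    if n_mirnas == 0:
        return 0.0
    return round_half_up(n_pairs / n_mirnas, 1)


def hits_to_frame(hits: list[TargetHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"mirna_id": h.mirna_id, "transcript_id": h.transcript_id,
             "expectation": h.expectation, "start": h.start, "end": h.end,
             "aln_mirna": h.aln_mirna, "aln_midline": h.aln_midline,
             "aln_site": h.aln_site}
            for h in hits
        ]
    )
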