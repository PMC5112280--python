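"""Position-weighted complementarity scoring and transcript scanning."""

import numpy as np
import pytest

from fiberma.seq import revcomp
from fiberma.targets import (
    ScoringScheme,
    exhaustive_scan,
    mean_targets_per_mirna,
    scan_transcripts,
    score_duplex,
    target_summary,
)

MIRNA = "TGACAGAAGAGAGTGAGCACA"  # 21 nt


def test_perfect_complement_scores_zero():
    e, states = score_duplex(MIRNA, revcomp(MIRNA))
    assert e == 0.0
    assert set(states) == {"match"}


def test_gu_wobble_position_weighting():
    site = list(revcomp(MIRNA))
    # miRNA position 15 pairs site index len-15; make it a G:U wobble
    p = 15
    m15 = MIRNA[p - 1]
    assert m15 in "GT"  # position 15 is T here; pair it with G
    site[len(site) - p] = "G" if m15 == "T" else "T"
    e, states = score_duplex(MIRNA, "".join(site))
    assert states[p - 1] == "GU"
    assert e == pytest.approx(0.5)  # outside the doubled seed region
    # same wobble moved into the seed (position 5) costs double
    site5 = list(revcomp(MIRNA))
    m5 = MIRNA[4]
    assert m5 in "GT" or True
    if m5 == "G":
        site5[len(site5) - 5] = "T"
    elif m5 == "T":
        site5[len(site5) - 5] = "G"
    else:  # make position 5 a mismatch-free wobble by editing the miRNA
        m = MIRNA[:4] + "G" + MIRNA[5:]
        site5 = list(revcomp(m))
        site5[len(site5) - 5] = "T"
        e5, st5 = score_duplex(m, "".join(site5))
        assert st5[4] == "GU" and e5 == pytest.approx(1.0)
        return
    e5, st5 = score_duplex(MIRNA, "".join(site5))
    assert st5[4] == "GU" and e5 == pytest.approx(1.0)


def test_score_matches_positionwise_oracle(rng):
    """Random pairs vs an independent per-position recomputation."""
    sch = ScoringScheme()
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for _ in range(200):
        m = "".join(rng.choice(list("ACGT"), size=21))
        s = "".join(rng.choice(list("ACGT"), size=21))
        e, _ = score_duplex(m, s)
        expect = 0.0
        for p in range(1, 22):
            mb, tb = m[p - 1], s[21 - p]
            if comp[mb] == tb:
                pen = 0.0
            elif (mb, tb) in (("G", "T"), ("T", "G")):
                pen = 0.5
            else:
                pen = 1.0
            expect += pen * (2.0 if 2 <= p <= 13 else 1.0)
        assert e == pytest.approx(expect, abs=1e-9)


def test_expectation_monotone_in_mismatches(rng):
    site = list(revcomp(MIRNA))
    prev = 0.0
    order = rng.permutation(len(site))
    for i in order[:8]:
        cur = list(site)
        cur[int(i)] = {"A": "C", "C": "A", "G": "A", "T": "C"}[site[int(i)]]
        e, _ = score_duplex(MIRNA, "".join(cur))
        assert e >= 0.5
        site = cur
        e_total, _ = score_duplex(MIRNA, "".join(site))
        assert e_total >= prev
        prev = e_total


def test_revcomp_symmetry_without_wobble():
    sch = ScoringScheme(seed_multiplier=1.0)  # uniform positional weights
    m = "ACACACACACACACACACACA"  # no G/T: wobble impossible in either role
    site = list(revcomp(m))
    # A:A mismatch maps to T:T under complementation - still a mismatch,
    # so the two orientations see identical pair states
    site[4] = "A"  # opposite miRNA position 17 (an A)
    s = "".join(site)
    e1, _ = score_duplex(m, s, sch)
    e2, _ = score_duplex(revcomp(s), revcomp(m), sch)
    assert e1 == pytest.approx(e2)


def test_planted_perfect_site_found_with_coordinates(rng):
    flank = "".join(rng.choice(list("ACG"), size=150))
    site = revcomp(MIRNA)
    transcript = flank + site + flank
    hits = scan_transcripts({"mir1": MIRNA}, {"t1": transcript})
    assert len(hits) == 1
    h = hits[0]
    assert (h.start, h.end, h.expectation) == (150, 150 + 21, 0.0)
    assert h.aln_midline == "|" * 21


def test_scanner_cutoff_contract(rng):
    transcripts = {
        f"t{i}": "".join(rng.choice(list("ACGT"), size=400)) for i in range(5)
    }
    hits = scan_transcripts({"mir1": MIRNA}, transcripts, max_expectation=3.0)
    assert all(h.expectation <= 3.0 for h in hits)


def test_seed_mismatch_sites_recovered_only_at_generous_cutoff(rng):
    sites = []
    transcripts = {}
    for i in range(6):
        site = list(revcomp(MIRNA))
        # one mismatch opposite miRNA position 5 (inside seed): penalty 2.0
        site[len(site) - 5] = {"A": "C", "C": "A", "G": "A", "T": "C"}[site[len(site) - 5]]
        flank = "".join(rng.choice(list("ACG"), size=100))
        transcripts[f"t{i}"] = flank + "".join(site) + flank
    loose = scan_transcripts({"mir1": MIRNA}, transcripts, max_expectation=3.0)
    tight = scan_transcripts({"mir1": MIRNA}, transcripts, max_expectation=1.5)
    found = {h.transcript_id for h in loose if abs(h.expectation - 2.0) < 1e-9}
    assert found == set(transcripts)
    assert not any(abs(h.expectation - 2.0) < 1e-9 for h in tight)


def test_scanner_equals_exhaustive_oracle_without_gaps(rng):
    transcript = "".join(rng.choice(list("ACGT"), size=1500))
    hits = scan_transcripts({"mir1": MIRNA}, {"t": transcript},
                            max_expectation=14.0, max_gaps=0)
    oracle = exhaustive_scan(MIRNA, transcript)
    best_by_start = {}
    for h in hits:
        best_by_start[h.start] = h.expectation
    # every reported hit must equal the oracle's window score
    for start, e in best_by_start.items():
        assert e == pytest.approx(dict(oracle)[start], abs=1e-9)
    # and the oracle's global best window must be reported
    best = min(oracle, key=lambda se: (se[1], se[0]))
    assert best[0] in best_by_start or any(
        not (best[0] + 21 <= h.start or best[0] >= h.end) for h in hits
    )


def test_single_gap_site_scored_with_gap_penalty(rng):
    flank = "".join(rng.choice(list("ACG"), size=80))
    site = revcomp(MIRNA)
    gapped = site[:10] + site[11:]  # delete one base opposite position ~12
    transcript = flank + gapped + flank
    hits = scan_transcripts({"mir1": MIRNA}, {"t": transcript},
                            max_expectation=6.0, max_gaps=1)
    assert hits, "gapped site should be recoverable with one gap allowed"
    assert any("gap" in h.states for h in hits)


def test_mean_targets_arithmetic():
    assert mean_targets_per_mirna(729, 94) == 7.8
    assert mean_targets_per_mirna(0, 0) == 0.0


def test_target_summary_with_synthetic_truth(rng):
    from fiberma.targets import TargetHit

    hits = []
    for i in range(5):
        for j in range(3):  # exactly 3 targets per miRNA
            hits.append(TargetHit(f"mir{i}", f"t{i}_{j}", 1.0, 0, 21))
    summ = target_summary(hits, [f"mir{i}" for i in range(5)] + ["mir_nohit"])
    assert summ["mean_targets_per_mirna"] == 3.0
    assert summ["zero_hit_mirnas"] == ["mir_nohit"]
    empty = target_summary([], ["a", "b"])
    assert empty["mean_targets_per_mirna"] == 0.0
    assert set(empty["zero_hit_mirnas"]) == {"a", "b"}
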