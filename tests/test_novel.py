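"""Hairpin folding, duplex-walk criteria, MFEI, locus seeding."""

import numpy as np
import pytest

from fiberma.annotate import AnnotatedLibrary, map_to_genome
from fiberma.errors import AlphabetError, InputError
from fiberma.folding import NussinovFolder, ViennaFolder, fold, pair_table
from fiberma.novel import (
    CandidateWindow,
    ClusterRead,
    HairpinThresholds,
    _duplex_walk,
    compute_mfei,
    evaluate_hairpin,
    novel_summary,
    seed_loci,
)
from fiberma.preprocess import ReadLibrary
from fiberma.seq import revcomp


@pytest.mark.parametrize("folder", [ViennaFolder(), NussinovFolder()])
def test_designed_hairpin_folds(folder):
    structure, mfe = folder.fold("GGGGAAAACCCC")
    assert structure.count("(") >= 4
    assert mfe < 0


def test_homopolymer_has_no_structure():
    structure, mfe = fold("A" * 50)
    assert set(structure) == {"."}
    assert mfe == 0.0


def test_fold_rejects_bad_alphabet():
    with pytest.raises(AlphabetError):
        fold("ACGTX" * 10)


def test_pair_table_roundtrip_and_errors():
    pt = pair_table("((..))")
    assert pt == [5, 4, -1, -1, 1, 0]
    for bad in ("((.", "...)", "(]"):
        with pytest.raises(InputError):
            pair_table(bad)


def test_perfect_precursor_pairs_mature_to_star():
    mature = "TGACAGAAGAGAGTGAGCACA"
    pre = mature + "GTTTTTTTTTTTTTTTTG" + revcomp(mature)
    structure, mfe = fold(pre)
    pt = pair_table(structure)
    star_lo = len(pre) - len(mature)
    paired = [pt[i] for i in range(len(mature)) if pt[i] >= 0]
    assert len(paired) >= len(mature) - 2
    assert all(p >= star_lo - 2 for p in paired)


def test_mfei_boundary_arithmetic():
    # |MFE| 42.5 over 100 nt at 50% GC sits exactly on the 0.85 boundary
    assert compute_mfei(-42.5, 100, 50.0) == pytest.approx(0.85)


def _structure_from_segments(segments):
    """Build a two-arm duplex structure from (paired?, u_m, u_s) segments.

    Returns (structure, mature_interval, expected_mismatches, expected_bulges).
    """
    left, right = [], []
    mism = bulges = 0
    for kind, u_m, u_s in segments:
        if kind == "pair":
            left.append("(")
            right.append(")")
        else:
            left.append("." * u_m)
            right.append("." * u_s)
            mism += min(u_m, u_s)
            if u_m != u_s:
                bulges += 1
    structure = "".join(left) + "...." + "".join(reversed(right))
    return structure, (0, len("".join(left))), mism, bulges


def test_duplex_walk_on_hand_constructed_bulges():
    segs = [("pair", 0, 0)] * 3 + [("loop", 2, 0)] + [("pair", 0, 0)] * 3 \
        + [("loop", 1, 1)] + [("pair", 0, 0)] * 3
    structure, (a, b), mism, bulges = _structure_from_segments(segs)
    pt = pair_table(structure)
    got_m, got_b, got_u = _duplex_walk(pt, a, b)
    assert (got_m, got_b) == (mism, bulges) == (1, 1)
    assert got_u == 3  # 2-base bulge + one mismatch base on the mature strand


def test_three_asymmetric_bulges_fail_criterion():
    segs = [("pair", 0, 0)] * 4
    for _ in range(3):
        segs += [("loop", 1, 0), ("pair", 0, 0), ("pair", 0, 0)]
    structure, (a, b), _, bulges = _structure_from_segments(segs)
    assert bulges == 3
    pt = pair_table(structure)
    _, got_b, _ = _duplex_walk(pt, a, b)
    assert got_b == 3  # > max_asymmetric_bulges default of 2


def test_bulge_counter_matches_randomized_construction_oracle(rng):
    """1000 random duplexes: walk results equal construction ground truth."""
    for _ in range(1000):
        segs = [("pair", 0, 0)]
        for _ in range(int(rng.integers(3, 12))):
            if rng.random() < 0.6:
                segs.append(("pair", 0, 0))
            else:
                u_m, u_s = int(rng.integers(0, 4)), int(rng.integers(0, 4))
                if u_m == 0 and u_s == 0:
                    u_m = 1
                segs.append(("loop", u_m, u_s))
                segs.append(("pair", 0, 0))
        structure, (a, b), mism, bulges = _structure_from_segments(segs)
        pt = pair_table(structure)
        got_m, got_b, _ = _duplex_walk(pt, a, b)
        assert (got_m, got_b) == (mism, bulges)


def _toy_candidate(extra_reads=()):
    mature = "TGACAGAAGAGAGTGAGCACA"
    loop = "GTTTAACGGTTTTTAG"
    pre = mature + loop + revcomp(mature)
    flank_l = "GAATCCGGTTAACCGGATTC"
    flank_r = "CCTTAAGGCCAATTGGCCTA"
    genome = {"chr1": flank_l + pre + flank_r}
    m0 = len(flank_l)
    reads = [ClusterRead(mature, m0, m0 + len(mature), {"L1": 40})]
    reads += list(extra_reads)
    win = CandidateWindow("chr1", "+", 0, len(genome["chr1"]), mature,
                          m0, m0 + len(mature), reads)
    return win, genome, m0, pre


def test_mfei_recorded_and_recomputable():
    win, genome, _, _ = _toy_candidate()
    cand = evaluate_hairpin(win, genome)
    recomputed = 100.0 * abs(cand.mfe) / (cand.length * cand.gc_percent)
    assert cand.mfei == pytest.approx(recomputed, abs=1e-6)
    assert cand.mfei_flag == (cand.mfei >= 0.85)


def test_dominance_decreases_with_outside_reads():
    win, genome, m0, pre = _toy_candidate()
    base = evaluate_hairpin(win, genome).dominance
    # a read over the loop region, outside mature/star +/- 2 nt
    outside = ClusterRead("ACGT" * 5, m0 + len("TGACAGAAGAGAGTGAGCACA") + 2,
                          m0 + len("TGACAGAAGAGAGTGAGCACA") + 22, {"L1": 10})
    win2, genome2, _, _ = _toy_candidate([outside])
    lower = evaluate_hairpin(win2, genome2).dominance
    assert 0.0 <= lower < base <= 1.0


def test_seed_loci_emits_two_windows_per_stack(rng):
    genome = "".join(rng.choice(list("ACGT"), size=3000))
    stack = genome[1000:1021]
    lib = AnnotatedLibrary(library=ReadLibrary("L1", {stack: 50}))
    map_to_genome(lib, genome)
    wins = seed_loci([lib], min_stack=5, window=250)
    assert len(wins) == 2
    lows = sorted(w.start for w in wins)
    assert lows[0] == max(0, 1000 - 250) and lows[1] == 1000 - 20


def test_stack_below_min_stack_not_seeded(rng):
    genome = "".join(rng.choice(list("ACGT"), size=2000))
    lib = AnnotatedLibrary(library=ReadLibrary("L1", {genome[500:521]: 3}))
    map_to_genome(lib, genome)
    assert seed_loci([lib], min_stack=5) == []


def test_seeded_windows_cover_embedded_loci(pipeline_run):
    _, out, state = pipeline_run
    import json

    with open(out / "sim" / "truth.json") as fh:
        loci = json.load(fh)["loci"]
    wins = seed_loci(state.annotated, state.assigned_known)
    novel = [l for l in loci if not l["known"]]
    covered = 0
    for l in novel:
        if any(w.start <= l["start"] and w.end >= l["end"] and w.chrom == l["chrom"]
               for w in wins):
            covered += 1
    assert covered >= len(novel) - 1


def test_novel_summary_single_call():
    tab = novel_summary(["TGACAGAAGAGAGTGAGCACA"])
    assert tab.loc["U", 21] == 1
    assert tab.loc["Total", "Total"] == 1
    assert tab.loc["U", "pct"] == 100.0
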