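"""RACE cleavage mapping, 2^-ddCt quantification and profile correlation."""

import numpy as np
import pandas as pd
import pytest

from fiberma.errors import InputError, PairingError, UndefinedCorrelationError
from fiberma.seq import revcomp
from fiberma.targets import TargetHit
from fiberma.validation import correlate, ddct, map_cleavage

MIRNA = "TGACAGAAGAGAGTGAGCACA"


def _site_hit(flank=50):
    site = revcomp(MIRNA)
    target = "A" * flank + site + "C" * flank
    hit = TargetHit("mir1", "t1", 0.0, flank, flank + len(site))
    return target, hit


def _clones(positions_1based):
    return pd.DataFrame(
        {"target_id": "t1",
         "clone_id": [f"c{i}" for i in range(len(positions_1based))],
         "five_prime_pos_1based": positions_1based}
    )


def test_all_clones_at_position_ten():
    target, hit = _site_hit()
    pos = hit.end - 10 + 1  # 1-based transcript coordinate opposite base 10
    cm = map_cleavage(_clones([pos] * 10), target, MIRNA, hit)
    assert cm.fractions == {10: 1.0}
    assert cm.canonical_fraction == 1.0
    assert cm.n_mapped == 10 and cm.n_unmapped == 0


def test_split_fractions():
    target, hit = _site_hit()
    p10 = hit.end - 10 + 1
    p12 = hit.end - 12 + 1
    cm = map_cleavage(_clones([p10] * 8 + [p12] * 3), target, MIRNA, hit)
    assert cm.fractions[10] == pytest.approx(8 / 11)
    assert cm.fractions[12] == pytest.approx(3 / 11)
    assert sum(cm.fractions.values()) == pytest.approx(1.0, abs=1e-9)


def test_clone_outside_flank_unmapped_and_beyond_transcript_errors():
    target, hit = _site_hit()
    cm = map_cleavage(_clones([1]), target, MIRNA, hit)  # far upstream
    assert cm.n_unmapped == 1 and cm.n_mapped == 0
    with pytest.raises(InputError):
        map_cleavage(_clones([len(target) + 5]), target, MIRNA, hit)


def _ct_rows(gene, sample, ct, n_bio=1, n_tech=1):
    return [
        {"gene": gene, "sample": sample, "bio_rep": b, "tech_rep": t, "ct": ct}
        for b in range(1, n_bio + 1) for t in range(1, n_tech + 1)
    ]


def test_ddct_worked_arithmetic():
    rows = (_ct_rows("g", "cal", 24) + _ct_rows("ref", "cal", 20)
            + _ct_rows("g", "s1", 25) + _ct_rows("ref", "s1", 20))
    out = ddct(pd.DataFrame(rows), "ref", "cal").set_index("sample")
    assert out.loc["s1", "rel_expr"] == pytest.approx(0.5)
    assert out.loc["s1", "ddct"] == pytest.approx(1.0)
    assert out.loc["cal", "rel_expr"] == pytest.approx(1.0)


def test_ddct_translation_invariance(rng):
    rows = []
    for s in ("cal", "s1", "s2"):
        for g in ("ref", "g"):
            for b in range(1, 4):
                for t in range(1, 4):
                    rows.append({"gene": g, "sample": s, "bio_rep": b,
                                 "tech_rep": t,
                                 "ct": float(20 + rng.normal(0, 1))})
    df = pd.DataFrame(rows)
    out1 = ddct(df, "ref", "cal")
    shifted = df.assign(ct=df["ct"] + 5.0)
    out2 = ddct(shifted, "ref", "cal")
    assert np.allclose(out1["rel_expr"], out2["rel_expr"], atol=1e-9)


def test_ddct_recovers_known_fold_changes():
    """Noise-free Ct tables built from known fold changes invert exactly."""
    folds = {"cal": 1.0, "s1": 0.25, "s2": 8.0}
    rows = []
    for s, f in folds.items():
        rows += _ct_rows("ref", s, 20.0, n_bio=3, n_tech=3)
        rows += _ct_rows("g", s, 24.0 - np.log2(f), n_bio=3, n_tech=3)
    out = ddct(pd.DataFrame(rows), "ref", "cal").set_index("sample")
    for s, f in folds.items():
        assert out.loc[s, "rel_expr"] == pytest.approx(f, abs=1e-9)
        assert out.loc[s, "rel_expr_sd"] == pytest.approx(0.0, abs=1e-12)


def test_ddct_missing_reference_is_pairing_error():
    rows = _ct_rows("g", "cal", 24)
    with pytest.raises(PairingError):
        ddct(pd.DataFrame(rows), "ref", "cal")


def test_correlation_signs_and_errors():
    r, anti = correlate([1, 2, 3, 4], [4, 3, 2, 1])
    assert r == pytest.approx(-1.0) and anti
    r, anti = correlate([1, 2, 3, 4], [1, 2, 3, 4])
    assert r == pytest.approx(1.0) and not anti
    with pytest.raises(UndefinedCorrelationError):
        correlate([1, 1, 1, 1], [1, 2, 3, 4])


def test_correlation_symmetric_and_scale_invariant(rng):
    x = rng.normal(size=4)
    y = rng.normal(size=4)
    r1, _ = correlate(x, y)
    r2, _ = correlate(y, x)
    r3, _ = correlate(x * 100 + 7, y)
    assert r1 == pytest.approx(r2) == pytest.approx(r3)


def test_anticorrelated_generator_profiles_mostly_negative():
    """Strength-0.9 anti-correlated pairs give r < 0 in >=95% of replicates."""
    from fiberma.simulate import ARCHETYPE_PROFILES

    neg = 0
    n = 100
    rng = np.random.default_rng(202)
    for _ in range(n):
        prof = np.array(ARCHETYPE_PROFILES["A"])
        inverted = prof.max() + prof.min() - prof
        s = 0.9
        target = (1 - s) * prof.mean() + s * inverted
        target = target * rng.normal(1.0, 0.05, size=4)
        mirna = prof * rng.normal(1.0, 0.05, size=4)
        r, _ = correlate(mirna, target)
        neg += r < 0
    assert neg >= 95
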