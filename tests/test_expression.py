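"""RPTM normalization, expression selection and temporal clustering."""

import numpy as np
import pandas as pd
import pytest

from fiberma.errors import ClusteringError, NormalizationError
from fiberma.expression import (
    cluster_profiles,
    dendrogram_newick,
    logfc_vs_mean,
    normalize_rptm,
    select_expressed,
)
from fiberma.simulate import ARCHETYPE_PROFILES

LIBS = ["5DPA", "10DPA", "15DPA", "20DPA"]


def _counts(rows):
    return pd.DataFrame(rows, columns=LIBS)


def test_identity_scale_normalization():
    m = normalize_rptm(_counts([[100, 0, 50, 10]]), dict.fromkeys(LIBS, 10**7), 1e7)
    assert np.allclose(m.iloc[0].tolist(), [100.0, 0.0, 50.0, 10.0], atol=1e-9)


def test_zero_total_is_error():
    with pytest.raises(NormalizationError):
        normalize_rptm(_counts([[1, 1, 1, 1]]), dict.fromkeys(LIBS, 0))


def test_normalization_matches_independent_recomputation(rng):
    counts = pd.DataFrame(rng.integers(0, 5000, size=(30, 4)), columns=LIBS)
    totals = {lab: int(t) for lab, t in zip(LIBS, rng.integers(10**5, 10**6, 4))}
    m = normalize_rptm(counts, totals, 1e7)
    # oracle: plain python arithmetic, cell by cell
    for i in range(counts.shape[0]):
        for j, lab in enumerate(LIBS):
            expect = counts.iloc[i, j] / totals[lab] * 1e7
            assert abs(m.iloc[i, j] - expect) < 1e-9


def test_normalization_is_linear(rng):
    counts = pd.DataFrame(rng.integers(0, 1000, size=(10, 4)), columns=LIBS)
    totals = dict.fromkeys(LIBS, 10**6)
    assert np.allclose(normalize_rptm(counts * 3, totals), 3 * normalize_rptm(counts, totals))


def test_selection_threshold_is_strict():
    m = pd.DataFrame([[5, 20, 99, 50], [0, 0, 101, 0]], columns=LIBS,
                     index=["drop", "keep"])
    kept = select_expressed(m, 100)
    assert list(kept.index) == ["keep"]
    assert kept.attrs == {"n_kept": 1, "n_dropped": 1}


def test_selection_matches_known_truth(rng):
    rows = np.vstack([rng.uniform(0, 99, size=(24, 4)),
                      rng.uniform(101, 500, size=(16, 4))])
    m = pd.DataFrame(rows, index=[f"m{i}" for i in range(40)], columns=LIBS)
    kept = select_expressed(m, 100)
    assert set(kept.index) == {f"m{i}" for i in range(24, 40)}


def test_archetype_rows_label_a_b_c_d():
    m = pd.DataFrame(
        [np.array(ARCHETYPE_PROFILES[c]) * 1000 for c in "ABCD"],
        index=list("abcd"), columns=LIBS,
    )
    labels, assignments, Z, _ = cluster_profiles(m, k=4)
    assert [labels[i] for i in "abcd"] == ["A", "B", "C", "D"]
    assert len(set(assignments.values())) == 4


def test_duplicate_rows_merge_first():
    m = pd.DataFrame(
        [[1000, 10, 10, 10], [1000, 10, 10, 10], [10, 1000, 10, 10],
         [10, 10, 10, 1000], [500, 400, 300, 200]],
        index=list("abcde"), columns=LIBS,
    )
    _, _, Z, _ = cluster_profiles(m, k=4)
    assert Z[0, 2] == 0.0  # first merge at height zero
    assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}


def test_merge_heights_monotone(rng):
    m = pd.DataFrame(rng.uniform(1, 1000, size=(25, 4)), columns=LIBS,
                     index=[f"m{i}" for i in range(25)])
    _, _, Z, _ = cluster_profiles(m, k=4)
    assert np.all(np.diff(Z[:, 2]) >= -1e-12)


def test_labels_invariant_to_row_identifiers(rng):
    vals = rng.uniform(1, 1000, size=(12, 4))
    m1 = pd.DataFrame(vals, index=[f"m{i}" for i in range(12)], columns=LIBS)
    m2 = pd.DataFrame(vals, index=[f"x{i}" for i in range(12)], columns=LIBS)
    l1, _, _, _ = cluster_profiles(m1)
    l2, _, _, _ = cluster_profiles(m2)
    assert [l1[f"m{i}"] for i in range(12)] == [l2[f"x{i}"] for i in range(12)]


def test_noisy_archetypes_recovered(rng):
    """40 synthetic profiles, 10 per archetype: >=90% labelled correctly."""
    rows, truth = [], []
    for c in "ABCD":
        base = np.array(ARCHETYPE_PROFILES[c])
        for _ in range(10):
            scale = rng.uniform(300, 3000)
            noise = rng.normal(1.0, 0.07, size=4)
            rows.append(base * scale * noise)
            truth.append(c)
    m = pd.DataFrame(rows, index=[f"m{i}" for i in range(40)], columns=LIBS)
    labels, _, _, _ = cluster_profiles(m, k=4)
    agree = sum(labels[f"m{i}"] == t for i, t in enumerate(truth)) / 40
    assert agree >= 0.9


def test_too_few_rows_raise():
    m = pd.DataFrame([[1, 2, 3, 4]], columns=LIBS, index=["only"])
    with pytest.raises(ClusteringError):
        cluster_profiles(m, k=4)


def test_logfc_of_flat_profile_is_zero():
    m = pd.DataFrame([[50.0, 50.0, 50.0, 50.0]], columns=LIBS)
    assert np.allclose(logfc_vs_mean(m).values, 0.0)


def test_dendrogram_newick_contains_all_leaves(rng):
    m = pd.DataFrame(rng.uniform(1, 100, size=(6, 4)), columns=LIBS,
                     index=[f"leaf{i}" for i in range(6)])
    _, _, Z, _ = cluster_profiles(m, k=2)
    nwk = dendrogram_newick(Z, list(m.index))
    assert nwk.endswith(";") and all(f"leaf{i}" in nwk for i in range(6))
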