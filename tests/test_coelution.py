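"""The five co-elution metrics: hand-worked values, symmetry, invariances."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from cofrac.coelution import (
    FEATURE_NAMES,
    apex_score,
    bayes_correlation_score,
    candidate_pairs,
    condition_profiles,
    euclidean_score,
    feature_table,
    jaccard_score,
    mutual_information_score,
    pairwise_features,
)
from cofrac.preprocess import filter_single_fraction, normalize

profiles = hnp.arrays(
    dtype=float,
    shape=st.integers(4, 24),
    elements=st.floats(0, 10, allow_nan=False),
)


def _paired(draw_len=12):
    return st.tuples(
        hnp.arrays(float, draw_len, elements=st.floats(0, 10)),
        hnp.arrays(float, draw_len, elements=st.floats(0, 10)),
    )


# -- hand-worked examples -------------------------------------------------


@pytest.mark.parametrize(
    "p1, p2, expected",
    [
        ([0.2, 0.5, 0.3], [0.2, 0.5, 0.3], 1.0),
        ([1, 0, 0], [0, 0, 1], 0.0),  # disjoint unit peaks: distance sqrt(2)
        ([0.5, 0.5, 0], [0.5, 0, 0.5], 0.5),  # 1 - sqrt(0.5)/sqrt(2)
    ],
)
def test_euclidean_hand_values(p1, p2, expected):
    assert euclidean_score(p1, p2) == pytest.approx(expected)


@pytest.mark.parametrize(
    "p1, p2, expected",
    [
        ([1, 2, 3, 0], [4, 5, 6, 0], 1.0),
        ([1, 0, 0], [0, 2, 2], 0.0),
        ([1, 1, 1, 0], [0, 1, 1, 1], 0.5),  # {0,1,2} vs {1,2,3}
        ([0, 0], [0, 0], 0.0),  # both-empty convention
    ],
)
def test_jaccard_hand_values(p1, p2, expected):
    assert jaccard_score(p1, p2) == pytest.approx(expected)


def test_apex_strict_equality_and_tie_break():
    assert apex_score([1, 3, 2], [1, 3, 2]) == 1.0
    ten = np.zeros(20); ten[10] = 1
    eleven = np.zeros(20); eleven[11] = 1
    assert apex_score(ten, eleven) == 0.0
    plateau = np.zeros(20); plateau[10] = plateau[11] = 5  # tie -> index 10
    assert apex_score(plateau, ten) == 1.0


def test_mutual_information_hand_values():
    # 4 points, 2 bins, joint counts (2,0;0,2) -> MI = ln 2
    assert mutual_information_score(
        [0, 0, 5, 5], [0, 0, 7, 7], n_bins=2
    ) == pytest.approx(math.log(2))
    # I(X;X) = H(X)
    p = np.array([0, 0, 1, 1, 4, 4.0])
    mi = mutual_information_score(p, p, n_bins=3)
    counts = np.array([2, 2, 2]) / 6
    assert mi == pytest.approx(float(-(counts * np.log(counts)).sum()))
    # constant profile carries no information
    assert mutual_information_score([2, 2, 2, 2], [0, 5, 1, 3]) == 0.0


def test_bayes_hand_values():
    assert bayes_correlation_score([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    # huge prior flattens the posterior -> degenerate convention
    assert bayes_correlation_score([1, 2, 3], [3, 1, 2], 1e15) == 0.5
    # zero prior reduces to plain Pearson mapped onto [0, 1]
    p1, p2 = [1.0, 4, 2, 0], [2.0, 3, 1, 1]
    r = np.corrcoef(np.array(p1) / 7, np.array(p2) / 7)[0, 1]
    assert bayes_correlation_score(p1, p2, 0.0) == pytest.approx((r + 1) / 2)


# -- candidate pairs ------------------------------------------------------


def test_candidate_pairs_counting():
    prof = pd.DataFrame(
        np.ones((10, 6)), index=[f"p{i:02d}" for i in range(10)]
    )
    assert len(candidate_pairs(prof, 2)) == 45  # C(10, 2)
    assert len(candidate_pairs(prof, 0)) == 45
    disjoint = pd.DataFrame(
        [[1, 1, 0, 0], [0, 0, 1, 1]], index=["a", "b"]
    )
    assert candidate_pairs(disjoint, 1) == []


# -- properties -----------------------------------------------------------


@settings(max_examples=60, deadline=None, derandomize=True)
@given(_paired())
def test_all_metrics_symmetric(pair):
    p1, p2 = pair
    for f in (
        euclidean_score,
        jaccard_score,
        apex_score,
        mutual_information_score,
        bayes_correlation_score,
    ):
        assert f(p1, p2) == pytest.approx(f(p2, p1))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(_paired(), st.randoms(use_true_random=False))
def test_permutation_invariance(pair, rnd):
    """Relabeling fractions identically leaves order-free metrics unchanged."""
    p1, p2 = pair
    perm = list(range(len(p1)))
    rnd.shuffle(perm)
    q1, q2 = p1[perm], p2[perm]
    for f in (
        euclidean_score,
        jaccard_score,
        mutual_information_score,
        bayes_correlation_score,
    ):
        assert f(p1, p2) == pytest.approx(f(q1, q2))


def test_feature_ranges_and_finiteness(bench):
    ft = bench.features
    assert np.isfinite(ft[list(FEATURE_NAMES)].to_numpy()).all()
    for col in ("jaccard", "apex", "euclidean", "bayes"):
        assert ft[col].between(0, 1).all()
    assert (ft["mutual_information"] >= 0).all()


def test_vectorized_features_match_scalar_reference():
    rng = np.random.default_rng(9)
    X = rng.uniform(0, 4, size=(7, 16))
    X[X < 1.0] = 0.0
    X = X / X.sum(axis=1, keepdims=True)
    prof = pd.DataFrame(X, index=[f"p{i}" for i in range(7)])
    table = pairwise_features(prof, min_overlap_fractions=0)
    scalar = {
        "euclidean": euclidean_score,
        "jaccard": jaccard_score,
        "apex": apex_score,
        "mutual_information": mutual_information_score,
        "bayes": bayes_correlation_score,
    }
    for _, row in table.iterrows():
        a, b = prof.loc[row["protein_a"]], prof.loc[row["protein_b"]]
        for name, f in scalar.items():
            assert row[name] == pytest.approx(f(a.to_numpy(), b.to_numpy())), name


def test_planted_pairs_separate_from_random_pairs(small_truth, small_data):
    """Per metric, intra-complex pairs average above random pairs."""
    matrices, design = small_data
    normalized = {}
    for ch in design["channel"]:
        kept, _ = filter_single_fraction(matrices[ch])
        normalized[ch] = normalize(kept)
    prof = condition_profiles(normalized, design, "cond1")
    table = pairwise_features(prof)
    intra = small_truth.intra_complex_pairs("cond1")
    is_intra = np.array(
        [
            frozenset((a, b)) in intra
            for a, b in zip(table["protein_a"], table["protein_b"])
        ]
    )
    assert is_intra.sum() >= 10
    for name in FEATURE_NAMES:
        assert table.loc[is_intra, name].mean() > table.loc[~is_intra, name].mean()


def test_feature_table_covers_all_conditions(small_data):
    matrices, design = small_data
    normalized = {}
    for ch in design["channel"]:
        kept, _ = filter_single_fraction(matrices[ch])
        normalized[ch] = normalize(kept)
    ft = feature_table(normalized, design)
    assert set(ft["condition"]) == set(design["condition"])
    # pairs are unordered-unique per condition
    dup = ft.duplicated(subset=["protein_a", "protein_b", "condition"])
    assert not dup.any()
    assert (ft["protein_a"] < ft["protein_b"]).all()
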