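"""Training-set construction, the forest contract and precision accounting."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from cofrac.classify import (
    PPINetwork,
    PrecisionReport,
    ReferenceComplexSet,
    attach_features,
    build_training_pairs,
    call_ppis,
    precision_fdr,
    train_classifier,
)
from cofrac.coelution import FEATURE_NAMES


def _ref(complexes: dict[str, set[str]]) -> ReferenceComplexSet:
    return ReferenceComplexSet({k: frozenset(v) for k, v in complexes.items()})


class _StubModel:
    """predict_proba returns the 'euclidean' column as the positive score."""

    classes_ = np.array([0, 1])

    def predict_proba(self, X):
        s = np.asarray(X)[:, 0]
        return np.column_stack([1 - s, s])


def _features_frame(rows):
    df = pd.DataFrame(rows, columns=["protein_a", "protein_b", "condition", "euclidean"])
    for name in FEATURE_NAMES[1:]:
        df[name] = 0.0
    return df


def test_single_complex_positive_enumeration():
    ref = _ref({"c1": {"a", "b", "c"}, "c2": {"x", "y"}})
    split = build_training_pairs(ref, ["a", "b", "c", "x", "y"], seed=0)
    pos = {
        tuple(r)
        for r in pd.concat([split.train, split.test])
        .query("label == 1")[["protein_a", "protein_b"]]
        .itertuples(index=False)
    }
    assert pos == {("a", "b"), ("a", "c"), ("b", "c"), ("x", "y")}


def test_negative_ratio_is_respected():
    proteins = [f"p{i:03d}" for i in range(160)]
    complexes = {
        f"c{k:02d}": set(proteins[8 * k : 8 * k + 4]) for k in range(20)
    }
    ref = _ref(complexes)
    split = build_training_pairs(
        ref, proteins, negative_ratio=5.0, test_fraction=0.3, seed=1
    )
    for side in (split.train, split.test):
        n_pos = int((side["label"] == 1).sum())
        n_neg = int((side["label"] == 0).sum())
        assert n_neg == 5 * n_pos


def test_complex_wise_split_has_no_pair_leakage():
    proteins = [f"p{i:03d}" for i in range(90)]
    complexes = {f"c{k}": set(proteins[9 * k : 9 * k + 5]) for k in range(10)}
    split = build_training_pairs(_ref(complexes), proteins, seed=3)
    assert not set(split.train_complexes) & set(split.test_complexes)
    train_pos = {
        tuple(r)
        for r in split.train.query("label == 1")[["protein_a", "protein_b"]]
        .itertuples(index=False)
    }
    test_pos = {
        tuple(r)
        for r in split.test.query("label == 1")[["protein_a", "protein_b"]]
        .itertuples(index=False)
    }
    assert not train_pos & test_pos


def test_too_few_complexes_refuse_to_train():
    ref = _ref({"c1": {"a", "b", "c"}})
    with pytest.raises(ValueError, match="usable reference complexes"):
        build_training_pairs(ref, ["a", "b", "c"], seed=0)


def test_restriction_drops_depleted_complexes():
    ref = _ref({"c1": {"a", "b", "c"}, "c2": {"x", "y", "z"}})
    restricted = ref.restricted(["a", "b", "x"], min_members=2)
    assert set(restricted.complexes) == {"c1"}


def test_reference_round_trip_and_union(tmp_path):
    ref = _ref({"c1": {"a", "b", "c"}, "c2": {"x", "y"}})
    ref.to_file(tmp_path / "ref.tsv")
    back = ReferenceComplexSet.from_file(tmp_path / "ref.tsv")
    assert back.complexes == ref.complexes
    dup = _ref({"other": {"a", "b", "c"}, "c3": {"q", "r"}})
    merged = ReferenceComplexSet.union([ref, dup])
    assert frozenset({"a", "b", "c"}) in merged.complexes.values()
    assert len(merged.complexes) == 3  # duplicate member set dropped


def test_separable_toy_problem_is_learned_perfectly():
    rng = np.random.default_rng(0)
    n = 120
    X = pd.DataFrame(
        {name: rng.uniform(0, 0.2, n) for name in FEATURE_NAMES}
    )
    y = np.zeros(n, dtype=int)
    y[: n // 2] = 1
    X.loc[: n // 2 - 1, "euclidean"] = rng.uniform(0.8, 1.0, n // 2)
    model = train_classifier(X, y, seed=0)
    Xt = pd.DataFrame({name: rng.uniform(0, 0.2, 40) for name in FEATURE_NAMES})
    Xt.loc[:19, "euclidean"] = rng.uniform(0.8, 1.0, 20)
    yt = np.array([1] * 20 + [0] * 20)
    pred = model.predict(np.asarray(Xt[list(FEATURE_NAMES)]))
    assert (pred == yt).all()


def test_shuffled_labels_give_chance_auc():
    rng = np.random.default_rng(7)
    n = 400
    X = pd.DataFrame({name: rng.uniform(0, 1, n) for name in FEATURE_NAMES})
    y = rng.permutation([0, 1] * (n // 2))
    model = train_classifier(X.iloc[: n // 2], y[: n // 2], seed=0)
    held = np.asarray(X.iloc[n // 2 :][list(FEATURE_NAMES)])
    scores = model.predict_proba(held)[:, 1]
    auc = roc_auc_score(y[n // 2 :], scores)
    assert abs(auc - 0.5) < 0.12  # Monte-Carlo tolerance at n=200


def test_same_seed_reproduces_identical_scores():
    rng = np.random.default_rng(5)
    X = pd.DataFrame({name: rng.uniform(0, 1, 80) for name in FEATURE_NAMES})
    y = (X["euclidean"] > 0.5).astype(int)
    s1 = train_classifier(X, y, seed=9).predict_proba(np.asarray(X))[:, 1]
    s2 = train_classifier(X, y, seed=9).predict_proba(np.asarray(X))[:, 1]
    np.testing.assert_array_equal(s1, s2)


def test_constant_features_warn_but_train():
    X = pd.DataFrame({name: [0.5] * 10 for name in FEATURE_NAMES})
    X["euclidean"] = [0.1] * 5 + [0.9] * 5
    y = [0] * 5 + [1] * 5
    with pytest.warns(UserWarning, match="constant"):
        train_classifier(X, y, seed=0)


def test_cutoff_boundary_is_inclusive():
    feats = _features_frame(
        [
            ("a", "b", "cond1", 0.625),
            ("a", "c", "cond1", 0.624999),
            ("b", "c", "cond1", 1.0),
        ]
    )
    net = call_ppis(_StubModel(), feats, cutoff=0.625)
    called = {
        (r.protein_a, r.protein_b) for r in net.called().itertuples()
    }
    assert called == {("a", "b"), ("b", "c")}


def test_impossible_cutoff_empties_network():
    feats = _features_frame([("a", "b", "cond1", 1.0)])
    net = call_ppis(_StubModel(), feats, cutoff=1.01)
    assert net.called().empty


def test_raising_cutoff_never_adds_calls():
    rng = np.random.default_rng(2)
    feats = _features_frame(
        [
            (f"p{i:02d}", f"q{i:02d}", "cond1", float(rng.uniform()))
            for i in range(50)
        ]
    )
    counts = [
        len(call_ppis(_StubModel(), feats, cutoff=c).called())
        for c in (0.2, 0.4, 0.6, 0.8)
    ]
    assert counts == sorted(counts, reverse=True)


def test_precision_fdr_accounting():
    ref = _ref({"c1": {"a", "b", "c"}})
    pairs = pd.DataFrame(
        {
            "protein_a": ["a", "a", "a"],
            "protein_b": ["b", "c", "z"],  # z outside the reference universe
            "condition": ["cond1"] * 3,
            "score": [0.9, 0.9, 0.9],
            "called": [True, True, True],
        }
    )
    report = precision_fdr(PPINetwork(pairs, 0.625), ref)
    assert report.n_called == 3
    assert report.n_evaluated == 2
    assert report.precision == pytest.approx(1.0)
    assert report.fdr == pytest.approx(0.0)


def test_precision_point_eight_means_fdr_point_two():
    report = PrecisionReport(n_called=10, n_evaluated=10, tp=8, fp=2)
    assert report.precision == pytest.approx(0.8)
    assert report.fdr == pytest.approx(0.2)


def test_empty_network_precision_is_not_applicable():
    ref = _ref({"c1": {"a", "b", "c"}})
    empty = PPINetwork(
        pd.DataFrame(
            columns=["protein_a", "protein_b", "condition", "score", "called"]
        ).astype({"called": bool}),
        0.625,
    )
    report = precision_fdr(empty, ref)
    assert report.precision is None
    assert report.fdr is None
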