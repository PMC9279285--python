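"""Supervised co-complex classification of protein pairs.

A random forest (library defaults, fixed seed) is trained on reference
complexes: positives are intra-complex pairs among detected proteins,
negatives are sampled pairs of detected reference proteins never
co-annotated, at a configurable ratio (default 5:1). The train/test split is
complex-wise — whole complexes are held out — so no test pair leaks into
training. Pairs scoring at or above the cutoff (default 0.625) are called
as interactions, per condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .coelution import FEATURE_NAMES

__all__ = [
    "DEFAULT_CUTOFF",
    "ReferenceComplexSet",
    "TrainTestPairs",
    "PPINetwork",
    "PrecisionReport",
    "build_training_pairs",
    "attach_features",
    "train_classifier",
    "score_pairs",
    "call_ppis",
    "precision_fdr",
]

DEFAULT_CUTOFF = 0.625


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ReferenceComplexSet:
    """Named gold-standard complexes used for training and evaluation."""

    complexes: dict[str, frozenset[str]]
    source: str = ""

    def __post_init__(self) -> None:
        if len(set(self.complexes)) != len(self.complexes):  # pragma: no cover
            raise ValueError("complex names must be unique")

    @classmethod
    def from_file(cls, path: str | Path, source: str = "") -> "ReferenceComplexSet":
        """Tab-delimited, one complex per line: name, then member ids."""
        path = Path(path)
        complexes: dict[str, frozenset[str]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                name, members = parts[0], [p for p in parts[1:] if p]
                if name in complexes:
                    raise ValueError(f"{path}:{lineno}: duplicate complex {name!r}")
                complexes[name] = frozenset(members)
        return cls(complexes=complexes, source=source or str(path))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.complexes):
                fh.write("\t".join([name, *sorted(self.complexes[name])]) + "\n")

    def restricted(self, proteins: Iterable[str], min_members: int = 2) -> "ReferenceComplexSet":
        """Intersect members with *proteins*, dropping depleted complexes."""
        universe = set(proteins)
        kept = {
            name: frozenset(m & universe)
            for name, m in self.complexes.items()
            if len(m & universe) >= min_members
        }
        return ReferenceComplexSet(complexes=kept, source=self.source)

    def proteins(self) -> set[str]:
        return set().union(*self.complexes.values()) if self.complexes else set()

    def intra_pairs(self) -> set[tuple[str, str]]:
        pairs: set[tuple[str, str]] = set()
        for members in self.complexes.values():
            mem = sorted(members)
            for i, a in enumerate(mem):
                for b in mem[i + 1 :]:
                    pairs.add((a, b))
        return pairs

    @staticmethod
    def union(
        sets: Sequence["ReferenceComplexSet"], source: str = "union"
    ) -> "ReferenceComplexSet":
        """Merge several references, dropping duplicate member sets.

        Identical member sets keep the first name encountered; name clashes
        with different members are disambiguated by suffixing the source.
        """
        complexes: dict[str, frozenset[str]] = {}
        seen: set[frozenset[str]] = set()
        for k, ref in enumerate(sets):
            for name in sorted(ref.complexes):
                members = ref.complexes[name]
                if members in seen:
                    continue
                seen.add(members)
                key = name if name not in complexes else f"{name}__{k}"
                complexes[key] = members
        return ReferenceComplexSet(complexes=complexes, source=source)


@dataclass(frozen=True)
class TrainTestPairs:
    """Complex-wise split of labeled pairs (label 1 = co-complex)."""

    train: pd.DataFrame
    test: pd.DataFrame
    train_complexes: tuple[str, ...]
    test_complexes: tuple[str, ...]


def _intra_pairs(ref: ReferenceComplexSet, names: Iterable[str]) -> set[tuple[str, str]]:
    pairs: set[tuple[str, str]] = set()
    for name in names:
        mem = sorted(ref.complexes[name])
        for i, a in enumerate(mem):
            for b in mem[i + 1 :]:
                pairs.add((a, b))
    return pairs


def _sample_negatives(
    proteins: Sequence[str],
    forbidden: set[tuple[str, str]],
    n: int,
    rng: np.random.Generator,
    pool: set[tuple[str, str]] | None = None,
) -> list[tuple[str, str]]:
    """Sample non-co-annotated pairs within *proteins*.

    When *pool* is given (the co-detected candidate pairs the classifier
    will actually score), negatives are drawn from it so the labeled ratio
    holds in the scored population; otherwise uniformly over all pairs.
    """
    universe = set(proteins)
    if pool is not None:
        eligible = sorted(
            p
            for p in pool
            if p[0] in universe and p[1] in universe and p not in forbidden
        )
        if len(eligible) <= n:
            return eligible
        idx = rng.choice(len(eligible), size=n, replace=False)
        return sorted(eligible[i] for i in sorted(idx))
    proteins = sorted(proteins)
    total = len(proteins) * (len(proteins) - 1) // 2
    available = total - sum(
        1 for p in forbidden if p[0] in universe and p[1] in universe
    )
    n = min(n, max(available, 0))
    out: set[tuple[str, str]] = set()
    attempts = 0
    while len(out) < n and attempts < 50 * n + 1000:
        i, j = rng.integers(len(proteins)), rng.integers(len(proteins))
        attempts += 1
        if i == j:
            continue
        pair = _canonical(proteins[i], proteins[j])
        if pair in forbidden or pair in out:
            continue
        out.add(pair)
    return sorted(out)


def build_training_pairs(
    reference: ReferenceComplexSet,
    detected: Iterable[str],
    negative_ratio: float = 5.0,
    test_fraction: float = 0.3,
    seed: int = 0,
    candidate_pool: Iterable[tuple[str, str]] | None = None,
) -> TrainTestPairs:
    """Labeled pair lists with a leakage-free complex-wise split.

    Positives are intra-complex pairs of detected proteins; negatives are
    sampled from each split's own protein universe among pairs never
    co-annotated anywhere in the reference. Passing the co-detected
    candidate pairs as *candidate_pool* restricts negative sampling to the
    population the classifier will actually score, which keeps the
    negative:positive ratio intact after features are attached. Any test
    positive also implied by a training complex (overlapping subunits) is
    removed from the test side, so train and test positives are disjoint by
    construction.
    """
    rng = np.random.default_rng(seed)
    ref = reference.restricted(detected, min_members=2)
    names = sorted(ref.complexes)
    if len(names) < 2:
        raise ValueError(
            f"need >= 2 usable reference complexes after restriction, "
            f"have {len(names)}"
        )
    order = list(rng.permutation(names))
    n_test = min(max(1, int(round(test_fraction * len(names)))), len(names) - 1)
    test_names = tuple(sorted(order[:n_test]))
    train_names = tuple(sorted(order[n_test:]))

    all_co = ref.intra_pairs()
    train_pos = _intra_pairs(ref, train_names)
    test_pos = _intra_pairs(ref, test_names) - train_pos
    pool = (
        {_canonical(a, b) for a, b in candidate_pool}
        if candidate_pool is not None
        else None
    )

    def make(names_: tuple[str, ...], pos: set[tuple[str, str]]) -> pd.DataFrame:
        universe = sorted(set().union(*(ref.complexes[n] for n in names_)))
        neg = _sample_negatives(
            universe, all_co, int(round(negative_ratio * len(pos))), rng, pool
        )
        rows = [(a, b, 1) for a, b in sorted(pos)] + [(a, b, 0) for a, b in neg]
        return pd.DataFrame(rows, columns=["protein_a", "protein_b", "label"])

    return TrainTestPairs(
        train=make(train_names, train_pos),
        test=make(test_names, test_pos),
        train_complexes=train_names,
        test_complexes=test_names,
    )


def attach_features(pairs: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Join labeled pairs with the per-condition feature table.

    Produces one row per (pair, condition) for which features exist; the
    label is carried along, so a pair contributes one training example per
    condition where both proteins were detected.
    """
    return pairs.merge(features, on=["protein_a", "protein_b"], how="inner")


def train_classifier(
    features: pd.DataFrame, labels: Sequence[int], seed: int = 0
) -> RandomForestClassifier:
    """Fit a random forest with library-default parameters and a fixed seed."""
    X = np.asarray(features[list(FEATURE_NAMES)], dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    constant = [
        name for name in FEATURE_NAMES if np.ptp(X[:, FEATURE_NAMES.index(name)]) == 0
    ]
    if constant:
        warnings.warn(
            f"constant training features: {constant}; training anyway",
            stacklevel=2,
        )
    model = RandomForestClassifier(random_state=seed)
    model.fit(X, y)
    return model


def score_pairs(model: RandomForestClassifier, features: pd.DataFrame) -> pd.Series:
    """Co-complex class probability in [0, 1] for each feature row."""
    X = np.asarray(features[list(FEATURE_NAMES)], dtype=float)
    pos = list(model.classes_).index(1)
    return pd.Series(model.predict_proba(X)[:, pos], index=features.index, name="score")


@dataclass(frozen=True)
class PPINetwork:
    """Per-condition scored pairs with a binary call at the cutoff."""

    pairs: pd.DataFrame  # protein_a, protein_b, condition, score, called
    cutoff: float = DEFAULT_CUTOFF

    def called(self, condition: str | None = None) -> pd.DataFrame:
        df = self.pairs[self.pairs["called"]]
        if condition is not None:
            df = df[df["condition"] == condition]
        return df

    def conditions(self) -> list[str]:
        return sorted(self.pairs["condition"].unique())


def call_ppis(
    model: RandomForestClassifier,
    features: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
) -> PPINetwork:
    """Score every (pair, condition) feature row and call at ``score >= cutoff``."""
    out = features[["protein_a", "protein_b", "condition"]].copy()
    out["score"] = score_pairs(model, features).to_numpy()
    out["called"] = out["score"] >= cutoff
    out = out.drop_duplicates(subset=["protein_a", "protein_b", "condition"])
    return PPINetwork(pairs=out.reset_index(drop=True), cutoff=cutoff)


@dataclass(frozen=True)
class PrecisionReport:
    """Precision/FDR of called pairs against reference co-complex pairs.

    Only called pairs whose both proteins occur in the reference universe
    are evaluated (the standard co-complex convention). ``precision`` is
    None when no called pair is eligible.
    """

    n_called: int
    n_evaluated: int
    tp: int
    fp: int

    @property
    def precision(self) -> float | None:
        if self.n_evaluated == 0:
            return None
        return self.tp / self.n_evaluated

    @property
    def fdr(self) -> float | None:
        p = self.precision
        return None if p is None else 1.0 - p


def precision_fdr(
    network: PPINetwork,
    reference: ReferenceComplexSet | set[tuple[str, str]],
    restrict_proteins: set[str] | None = None,
) -> PrecisionReport:
    """Evaluate called pairs against reference co-complex membership."""
    if isinstance(reference, ReferenceComplexSet):
        ref_pairs = reference.intra_pairs()
        universe = reference.proteins()
    else:
        ref_pairs = {(_canonical(a, b)) for a, b in reference}
        universe = {p for pair in ref_pairs for p in pair}
    if restrict_proteins is not None:
        universe = universe & restrict_proteins if universe else set(restrict_proteins)
    called = network.called()
    n_called = len(called)
    mask = called["protein_a"].isin(universe) & called["protein_b"].isin(universe)
    eligible = called[mask]
    tp = sum(
        1
        for a, b in zip(eligible["protein_a"], eligible["protein_b"])
        if _canonical(a, b) in ref_pairs
    )
    return PrecisionReport(
        n_called=n_called, n_evaluated=len(eligible), tp=tp, fp=len(eligible) - tp
    )
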