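"""Complex-prediction quality metrics and their Composite sum.

Predicted catalogs are compared to reference complexes with three
established metrics: the Maximum Matching Ratio (total weight of the
maximum bipartite matching between reference and predicted complexes under
the overlap score omega, divided by the number of reference complexes), the
Overlap (fraction of reference complexes matched by at least one prediction
at omega >= omega_min) and the geometric-mean Accuracy sqrt(Sn * PPV) from
the reference x prediction confusion matrix. The Composite Score is their
unweighted sum, on [0, 3]. Simpson's similarity index
``|A & B| / min(|A|, |B|)`` serves for annotation matching and
cross-condition comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "DEFAULT_OMEGA_MIN",
    "EvaluationReport",
    "overlap_omega",
    "simpson_index",
    "maximum_matching_ratio",
    "overlap_metric",
    "accuracy_metric",
    "composite_score",
    "evaluate_catalog",
]

DEFAULT_OMEGA_MIN = 0.25


def overlap_omega(a: Iterable[str], b: Iterable[str]) -> float:
    """omega(A, B) = |A & B|^2 / (|A| * |B|)."""
    a, b = set(a), set(b)
    if not a or not b:
        return 0.0
    return len(a & b) ** 2 / (len(a) * len(b))


def simpson_index(a: Iterable[str], b: Iterable[str]) -> float:
    """SI(A, B) = |A & B| / min(|A|, |B|); undefined for an empty set."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("Simpson index is undefined for an empty set")
    return len(a & b) / min(len(a), len(b))


def _as_sets(catalog: Mapping[str, Iterable[str]] | Sequence[Iterable[str]]):
    if isinstance(catalog, Mapping):
        return [set(catalog[k]) for k in sorted(catalog)]
    return [set(c) for c in catalog]


def _omega_matrix(
    reference: Sequence[set], predicted: Sequence[set], omega_min: float
) -> np.ndarray:
    W = np.zeros((len(reference), len(predicted)))
    for i, r in enumerate(reference):
        for j, p in enumerate(predicted):
            w = overlap_omega(r, p)
            if w >= omega_min:
                W[i, j] = w
    return W


def maximum_matching_ratio(
    predicted: Mapping[str, Iterable[str]] | Sequence[Iterable[str]],
    reference: Mapping[str, Iterable[str]] | Sequence[Iterable[str]],
    omega_min: float = DEFAULT_OMEGA_MIN,
) -> float:
    """Max-weight bipartite matching total over the reference count."""
    ref = _as_sets(reference)
    pred = _as_sets(predicted)
    if not ref:
        raise ValueError("MMR is undefined for an empty reference")
    if not pred:
        return 0.0
    W = _omega_matrix(ref, pred, omega_min)
    ri, pj = linear_sum_assignment(W, maximize=True)
    return float(W[ri, pj].sum() / len(ref))


def overlap_metric(
    predicted: Mapping[str, Iterable[str]] | Sequence[Iterable[str]],
    reference: Mapping[str, Iterable[str]] | Sequence[Iterable[str]],
    omega_min: float = DEFAULT_OMEGA_MIN,
) -> float:
    """Fraction of reference complexes matched by >= 1 prediction."""
    ref = _as_sets(reference)
    pred = _as_sets(predicted)
    if not ref:
        raise ValueError("Overlap is undefined for an empty reference")
    if not pred:
        return 0.0
    matched = sum(
        1 for r in ref if any(overlap_omega(r, p) >= omega_min for p in pred)
    )
    return matched / len(ref)


def accuracy_metric(
    predicted: Mapping[str, Iterable[str]] | Sequence[Iterable[str]],
    reference: Mapping[str, Iterable[str]] | Sequence[Iterable[str]],
) -> float:
    """Geometric mean of clustering-wise sensitivity and PPV.

    With T(i, j) = |reference_i & predicted_j|:
    Sn = sum_i max_j T(i, j) / sum_i |reference_i|,
    PPV = sum_j max_i T(i, j) / sum_j sum_i T(i, j).
    """
    ref = _as_sets(reference)
    pred = _as_sets(predicted)
    if not ref:
        raise ValueError("Accuracy is undefined for an empty reference")
    if not pred:
        return 0.0
    T = np.array([[len(r & p) for p in pred] for r in ref], dtype=float)
    ref_sizes = sum(len(r) for r in ref)
    sn = T.max(axis=1).sum() / ref_sizes if ref_sizes else 0.0
    col_total = T.sum()
    ppv = T.max(axis=0).sum() / col_total if col_total > 0 else 0.0
    return float(np.sqrt(sn * ppv))


@dataclass(frozen=True)
class EvaluationReport:
    """The three component metrics, their Composite sum and the matches."""

    mmr: float
    overlap: float
    accuracy: float
    matches: pd.DataFrame

    @property
    def composite(self) -> float:
        return self.mmr + self.overlap + self.accuracy

    def summary(self) -> str:
        return (
            f"MMR={self.mmr:.3f} Overlap={self.overlap:.3f} "
            f"Accuracy={self.accuracy:.3f} Composite={self.composite:.3f}"
        )


def composite_score(report: EvaluationReport) -> float:
    """Unweighted sum of MMR, Overlap and Accuracy."""
    return report.composite


def evaluate_catalog(
    predicted: Mapping[str, Iterable[str]] | Sequence[Iterable[str]],
    reference: Mapping[str, Iterable[str]],
    omega_min: float = DEFAULT_OMEGA_MIN,
) -> EvaluationReport:
    """Full evaluation of a predicted catalog against named references.

    The per-complex match table lists, for every reference complex, its
    best-omega predicted partner (if any above *omega_min*).
    """
    ref_names = sorted(reference)
    ref_sets = [set(reference[k]) for k in ref_names]
    pred_list = _as_sets(predicted)
    pred_names = (
        sorted(predicted) if isinstance(predicted, Mapping) else
        [f"pred_{j + 1}" for j in range(len(pred_list))]
    )
    rows = []
    for name, r in zip(ref_names, ref_sets):
        best_w, best_j = 0.0, None
        for j, p in enumerate(pred_list):
            w = overlap_omega(r, p)
            if w > best_w:
                best_w, best_j = w, j
        rows.append(
            {
                "reference": name,
                "best_predicted": pred_names[best_j] if best_j is not None else "",
                "omega": best_w,
                "matched": best_w >= omega_min,
            }
        )
    matches = pd.DataFrame(
        rows, columns=["reference", "best_predicted", "omega", "matched"]
    )
    return EvaluationReport(
        mmr=maximum_matching_ratio(pred_list, ref_sets, omega_min),
        overlap=overlap_metric(pred_list, ref_sets, omega_min),
        accuracy=accuracy_metric(pred_list, ref_sets),
        matches=matches,
    )
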