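"""The five pairwise co-elution similarity features.

Euclidean, Bayes, Jaccard, Apex and mutual-information scores between
protein elution profiles. The profiles are row-normalized elution vectors;
within a condition the replicate channels are concatenated, so a 192-fraction
duplicate design yields 384-point profiles.

Exact definitions (frozen here; each is a pluggable strategy):

* ``euclidean``: ``1 - d/sqrt(2)`` with *d* the Euclidean distance between
  the two unit-sum profiles; ``sqrt(2)`` is the largest possible distance
  between nonnegative unit-sum vectors, so the score lies in [0, 1].
* ``jaccard``: ``|A & B| / |A | B|`` over the sets of fractions with
  intensity > 0 (0 by convention when both sets are empty).
* ``apex``: 1 when the two argmax fractions coincide, else 0; plateau ties
  resolve to the lowest fraction index.
* ``mutual_information``: discrete MI (natural log) between equal-width
  intensity-binned profiles; zero intensities occupy their own bin; the
  default bin count is ``ceil(sqrt(n_points))``.
* ``bayes``: Pearson correlation of posterior-mean profiles under a uniform
  Dirichlet prior (pseudocount added to count-scaled profiles), mapped to
  [0, 1] via ``(r + 1)/2``; zero-variance posteriors score 0.5. Since
  Pearson is affine-invariant, any finite pseudocount leaves the score equal
  to plain Pearson on [0, 1]; the prior only acts through the degenerate
  (uniform-posterior) convention.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .preprocess import NormalizedMatrix

__all__ = [
    "FEATURE_NAMES",
    "condition_profiles",
    "candidate_pairs",
    "euclidean_score",
    "jaccard_score",
    "apex_score",
    "mutual_information_score",
    "bayes_correlation_score",
    "pairwise_features",
    "feature_table",
]

FEATURE_NAMES = ("euclidean", "bayes", "jaccard", "apex", "mutual_information")

_SQRT2 = math.sqrt(2.0)


def _as_df(matrix: pd.DataFrame | NormalizedMatrix) -> pd.DataFrame:
    return matrix.data if isinstance(matrix, NormalizedMatrix) else matrix


def condition_profiles(
    matrices: Mapping[str, pd.DataFrame | NormalizedMatrix],
    design: pd.DataFrame,
    condition: str,
) -> pd.DataFrame:
    """Concatenate a condition's replicate channels into one profile matrix.

    Only proteins retained in every replicate channel are kept; the
    concatenated profile is rescaled to unit sum so distance-based metrics
    keep their [0, 1] calibration.
    """
    rows = design[design["condition"] == condition]
    if rows.empty:
        raise ValueError(f"condition {condition!r} not in design")
    channels = list(rows["channel"])
    frames = [_as_df(matrices[ch]) for ch in channels]
    shared = sorted(set.intersection(*(set(f.index) for f in frames)))
    if not shared:
        raise ValueError(f"no protein detected in all channels of {condition!r}")
    parts = []
    for ch, f in zip(channels, frames):
        part = f.loc[shared]
        part = part.rename(columns={c: f"{ch}_{c}" for c in part.columns})
        parts.append(part)
    out = pd.concat(parts, axis=1)
    total = out.to_numpy().sum(axis=1, keepdims=True)
    out = pd.DataFrame(
        out.to_numpy() / np.where(total > 0, total, 1.0),
        index=out.index,
        columns=out.columns,
    )
    out.index.name = "protein_id"
    return out


def candidate_pairs(
    profiles: pd.DataFrame, min_overlap_fractions: int = 2
) -> list[tuple[str, str]]:
    """Unordered pairs co-detected in at least *min_overlap_fractions*."""
    det = (profiles.to_numpy() > 0).astype(np.float32)
    overlap = det @ det.T
    ids = list(profiles.index)
    iu, ju = np.triu_indices(len(ids), k=1)
    mask = overlap[iu, ju] >= min_overlap_fractions
    return [(ids[i], ids[j]) for i, j in zip(iu[mask], ju[mask])]


# ---------------------------------------------------------------------------
# scalar metrics (reference semantics; the vectorized path must agree)
# ---------------------------------------------------------------------------


def _unit(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    s = p.sum()
    return p / s if s > 0 else p


def euclidean_score(p1: Sequence[float], p2: Sequence[float]) -> float:
    a, b = _unit(p1), _unit(p2)
    d = float(np.linalg.norm(a - b))
    return float(np.clip(1.0 - d / _SQRT2, 0.0, 1.0))


def jaccard_score(p1: Sequence[float], p2: Sequence[float]) -> float:
    a = np.asarray(p1) > 0
    b = np.asarray(p2) > 0
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def apex_score(p1: Sequence[float], p2: Sequence[float]) -> float:
    # np.argmax returns the first maximal index: the lowest-index tie-break
    return 1.0 if int(np.argmax(p1)) == int(np.argmax(p2)) else 0.0


def _bin_profile(p: np.ndarray, n_bins: int) -> np.ndarray:
    """Zero gets bin 0; positive values fill ``n_bins - 1`` equal-width bins
    over (0, max]."""
    p = np.asarray(p, dtype=float)
    out = np.zeros(p.shape, dtype=np.int64)
    vmax = p.max()
    if vmax <= 0 or n_bins < 2:
        return out
    pos = p > 0
    idx = np.ceil(p[pos] / vmax * (n_bins - 1)).astype(np.int64)
    out[pos] = np.clip(idx, 1, n_bins - 1)
    return out


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    return float(-xlogy(p, p).sum())


def mutual_information_score(
    p1: Sequence[float], p2: Sequence[float], n_bins: int | None = None
) -> float:
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("profiles differ in length")
    n = len(p1)
    if n_bins is None:
        n_bins = max(2, math.ceil(math.sqrt(n)))
    b1 = _bin_profile(p1, n_bins)
    b2 = _bin_profile(p2, n_bins)
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (b1, b2), 1.0)
    h1 = _entropy_from_counts(joint.sum(axis=1))
    h2 = _entropy_from_counts(joint.sum(axis=0))
    h12 = _entropy_from_counts(joint.ravel())
    return max(0.0, h1 + h2 - h12)


def bayes_correlation_score(
    p1: Sequence[float], p2: Sequence[float], prior_pseudocount: float = 1.0
) -> float:
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n = len(p1)

    def posterior(p: np.ndarray) -> np.ndarray:
        s = p.sum()
        counts = p / s * n if s > 0 else np.zeros_like(p)
        return (counts + prior_pseudocount) / (n + n * prior_pseudocount)

    a, b = posterior(p1), posterior(p2)
    # relative spread; a posterior flattened by a huge prior is degenerate
    if a.std() <= 1e-12 * max(a.mean(), 1e-300) or b.std() <= 1e-12 * max(
        b.mean(), 1e-300
    ):
        return 0.5
    r = float(np.corrcoef(a, b)[0, 1])
    return float(np.clip((r + 1.0) / 2.0, 0.0, 1.0))


# ---------------------------------------------------------------------------
# vectorized all-pairs computation
# ---------------------------------------------------------------------------


def _pairwise_euclidean(X: np.ndarray) -> np.ndarray:
    s = X.sum(axis=1, keepdims=True)
    X = X / np.where(s > 0, s, 1.0)
    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    d = np.sqrt(np.clip(d2, 0.0, None))
    return np.clip(1.0 - d / _SQRT2, 0.0, 1.0)


def _pairwise_jaccard(X: np.ndarray) -> np.ndarray:
    det = (X > 0).astype(np.float32)
    inter = det @ det.T
    n = det.sum(axis=1)
    union = n[:, None] + n[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        j = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return j.astype(float)


def _pairwise_apex(X: np.ndarray) -> np.ndarray:
    apex = X.argmax(axis=1)
    return (apex[:, None] == apex[None, :]).astype(float)


def _pairwise_bayes(X: np.ndarray, prior_pseudocount: float) -> np.ndarray:
    n = X.shape[1]
    s = X.sum(axis=1, keepdims=True)
    counts = np.where(s > 0, X / np.where(s > 0, s, 1.0) * n, 0.0)
    post = (counts + prior_pseudocount) / (n + n * prior_pseudocount)
    sd = post.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(post)
    out = np.clip((r + 1.0) / 2.0, 0.0, 1.0)
    degenerate = sd <= 1e-12 * np.maximum(post.mean(axis=1), 1e-300)
    out[degenerate, :] = 0.5
    out[:, degenerate] = 0.5
    np.fill_diagonal(out, 1.0)
    out[np.ix_(degenerate, degenerate)] = 0.5
    return out


def _pairwise_mi(X: np.ndarray, n_bins: int | None) -> np.ndarray:
    n, m = X.shape
    if n_bins is None:
        n_bins = max(2, math.ceil(math.sqrt(m)))
    binned = np.vstack([_bin_profile(row, n_bins) for row in X])
    # marginal entropies
    H = np.empty(n)
    indicators = []
    for b in range(n_bins):
        indicators.append((binned == b).astype(np.float32))
    counts = np.stack([ind.sum(axis=1) for ind in indicators], axis=1)
    p = counts / m
    H = -xlogy(p, p).sum(axis=1)
    # joint entropy accumulated over bin pairs via indicator products
    Hj = np.zeros((n, n))
    for b1 in range(n_bins):
        A = indicators[b1]
        if not A.any():
            continue
        for b2 in range(n_bins):
            B = indicators[b2]
            if not B.any():
                continue
            C = (A @ B.T) / m
            Hj -= xlogy(C, C)
    mi = H[:, None] + H[None, :] - Hj
    return np.clip(mi, 0.0, None)


def pairwise_features(
    profiles: pd.DataFrame,
    pairs: Iterable[tuple[str, str]] | None = None,
    min_overlap_fractions: int = 2,
    n_bins: int | None = None,
    prior_pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Compute the five co-elution features for candidate pairs.

    *profiles* is a protein x point matrix (e.g. from
    :func:`condition_profiles`). When *pairs* is None, candidate pairs with
    at least *min_overlap_fractions* co-detected points are used.
    """
    X = profiles.to_numpy(dtype=float)
    ids = list(profiles.index)
    pos = {p: i for i, p in enumerate(ids)}
    if pairs is None:
        pairs = candidate_pairs(profiles, min_overlap_fractions)
    pairs = list(pairs)
    if not pairs:
        return pd.DataFrame(columns=["protein_a", "protein_b", *FEATURE_NAMES])
    eu = _pairwise_euclidean(X)
    ba = _pairwise_bayes(X, prior_pseudocount)
    ja = _pairwise_jaccard(X)
    ap = _pairwise_apex(X)
    mi = _pairwise_mi(X, n_bins)
    ii = np.array([pos[a] for a, _ in pairs])
    jj = np.array([pos[b] for _, b in pairs])
    out = pd.DataFrame(
        {
            "protein_a": [min(a, b) for a, b in pairs],
            "protein_b": [max(a, b) for a, b in pairs],
            "euclidean": eu[ii, jj],
            "bayes": ba[ii, jj],
            "jaccard": ja[ii, jj],
            "apex": ap[ii, jj],
            "mutual_information": mi[ii, jj],
        }
    )
    return out


def feature_table(
    matrices: Mapping[str, pd.DataFrame | NormalizedMatrix],
    design: pd.DataFrame,
    min_overlap_fractions: int = 2,
    n_bins: int | None = None,
    prior_pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-condition pair feature table over concatenated replicate profiles.

    Returns one row per (pair, condition) with the five feature columns.
    """
    frames = []
    for condition in design["condition"].unique():
        prof = condition_profiles(matrices, design, condition)
        feats = pairwise_features(
            prof,
            min_overlap_fractions=min_overlap_fractions,
            n_bins=n_bins,
            prior_pseudocount=prior_pseudocount,
        )
        feats.insert(2, "condition", condition)
        frames.append(feats)
    return pd.concat(frames, ignore_index=True)
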