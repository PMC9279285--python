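"""Matrix filtering, normalization and replicate reproducibility.

Proteins seen in a single fraction carry no co-elution information and are
discarded. Normalization is column-then-row: fraction (column) totals are
equalized to remove fraction bias, then each profile is scaled to unit sum
so similarity metrics compare elution *shape* independent of abundance.
Abundance comparisons use :func:`joint_column_normalize`, which equalizes
per-fraction totals with one factor shared across all multiplex channels so
cross-channel reporter-ion ratios survive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "NormalizedMatrix",
    "ReplicateAgreement",
    "filter_single_fraction",
    "normalize",
    "column_normalize",
    "row_normalize",
    "joint_column_normalize",
    "replicate_pearson",
]


@dataclass(frozen=True)
class NormalizedMatrix:
    """An elution matrix plus the ordered list of transforms applied."""

    data: pd.DataFrame
    transforms: tuple[str, ...]
    #: columns with zero total signal, left unscaled
    zero_columns: tuple[str, ...] = ()


def filter_single_fraction(
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop proteins detected in fewer than two fractions.

    Returns ``(kept, report)`` where *report* lists removed proteins with a
    reason (``all_zero`` or ``single_fraction``).
    """
    if matrix.empty:
        raise ValueError("matrix is empty")
    nonzero = (matrix.to_numpy() > 0).sum(axis=1)
    keep = nonzero >= 2
    reasons = np.where(nonzero == 0, "all_zero", "single_fraction")
    report = pd.DataFrame(
        {"protein_id": matrix.index[~keep], "reason": reasons[~keep]}
    ).reset_index(drop=True)
    return matrix.loc[keep], report


def column_normalize(matrix: pd.DataFrame) -> NormalizedMatrix:
    """Scale every nonzero column to the mean column total."""
    values = matrix.to_numpy(dtype=float)
    colsum = values.sum(axis=0)
    target = colsum.mean()
    factor = np.ones_like(colsum)
    nonzero = colsum > 0
    factor[nonzero] = target / colsum[nonzero]
    out = pd.DataFrame(values * factor, index=matrix.index, columns=matrix.columns)
    return NormalizedMatrix(
        data=out,
        transforms=("column_total_scaling",),
        zero_columns=tuple(matrix.columns[~nonzero]),
    )


def row_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale every nonzero row to unit sum (profile as a distribution)."""
    values = matrix.to_numpy(dtype=float)
    rowsum = values.sum(axis=1, keepdims=True)
    safe = np.where(rowsum > 0, rowsum, 1.0)
    return pd.DataFrame(values / safe, index=matrix.index, columns=matrix.columns)


def normalize(matrix: pd.DataFrame) -> NormalizedMatrix:
    """Column-then-row normalization of a filtered elution matrix."""
    col = column_normalize(matrix)
    out = row_normalize(col.data)
    return NormalizedMatrix(
        data=out,
        transforms=col.transforms + ("row_sum_to_one",),
        zero_columns=col.zero_columns,
    )


def joint_column_normalize(
    matrices: Mapping[str, pd.DataFrame],
) -> dict[str, pd.DataFrame]:
    """Equalize per-fraction totals with one factor shared by all channels.

    The total signal of each fraction, summed over every channel of the
    multiplex, is scaled to the mean fraction total. Because all channels of
    a fraction share one factor, the cross-channel ratios that encode
    relative abundance are preserved exactly.
    """
    if not matrices:
        raise ValueError("no matrices given")
    channels = sorted(matrices)
    cols = matrices[channels[0]].columns
    totals = np.zeros(len(cols))
    for ch in channels:
        if not matrices[ch].columns.equals(cols):
            raise ValueError(f"channel {ch!r} has mismatched fraction columns")
        totals += matrices[ch].to_numpy(dtype=float).sum(axis=0)
    target = totals.mean()
    factor = np.where(totals > 0, target / np.where(totals > 0, totals, 1.0), 1.0)
    return {
        ch: pd.DataFrame(
            matrices[ch].to_numpy(dtype=float) * factor,
            index=matrices[ch].index,
            columns=cols,
        )
        for ch in channels
    }


@dataclass(frozen=True)
class ReplicateAgreement:
    """Per-protein Pearson r between two replicate channels.

    Profiles with zero variance in either replicate have no defined r; they
    are excluded from the average and counted in ``excluded``. Both r and
    r^2 summaries are reported.
    """

    per_protein: pd.Series
    #: proteins with undefined r (zero variance in a replicate)
    excluded: tuple[str, ...]
    #: proteins present in only one replicate, dropped before comparison
    dropped: tuple[str, ...]

    @property
    def mean_r(self) -> float:
        return float(self.per_protein.mean()) if len(self.per_protein) else float("nan")

    @property
    def mean_r_squared(self) -> float:
        if not len(self.per_protein):
            return float("nan")
        return float((self.per_protein**2).mean())


def replicate_pearson(
    matrix_r1: pd.DataFrame | NormalizedMatrix,
    matrix_r2: pd.DataFrame | NormalizedMatrix,
) -> ReplicateAgreement:
    """Row-wise Pearson correlation over the shared protein set."""
    a = matrix_r1.data if isinstance(matrix_r1, NormalizedMatrix) else matrix_r1
    b = matrix_r2.data if isinstance(matrix_r2, NormalizedMatrix) else matrix_r2
    shared = sorted(set(a.index) & set(b.index))
    dropped = tuple(sorted(set(a.index) ^ set(b.index)))
    if not shared:
        raise ValueError("replicates share no proteins")
    x = a.loc[shared].to_numpy(dtype=float)
    y = b.loc[shared].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=1))
    defined = (sx > 0) & (sy > 0)
    r = np.full(len(shared), np.nan)
    r[defined] = (xc * yc).sum(axis=1)[defined] / (sx * sy)[defined]
    r = np.clip(r, -1.0, 1.0)
    per = pd.Series(r[defined], index=np.asarray(shared)[defined], name="pearson_r")
    excluded = tuple(np.asarray(shared)[~defined])
    return ReplicateAgreement(per_protein=per, excluded=excluded, dropped=dropped)
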