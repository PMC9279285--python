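"""Reading and writing the wide TSV elution-matrix dialect.

One TSV per channel (``protein_id`` then ``frac_0001..frac_NNNN``) plus a
``design.tsv`` mapping channels to (condition, replicate). Parsing is
strict: ragged rows, duplicate protein ids and non-numeric cells raise
:class:`MatrixParseError` naming the offending file and line.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .synth import FRACTION_PREFIX

__all__ = ["MatrixParseError", "write_matrices", "read_matrices", "read_matrix"]

DESIGN_FILE = "design.tsv"


class MatrixParseError(ValueError):
    """A matrix or design file violates the expected dialect."""


def write_matrices(
    matrices: Mapping[str, pd.DataFrame], design: pd.DataFrame, path: str | Path
) -> Path:
    """Persist channel matrices and the channel design under *path*."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    missing = set(design["channel"]) - set(matrices)
    if missing:
        raise ValueError(f"design references unknown channels: {sorted(missing)}")
    design.to_csv(path / DESIGN_FILE, sep="\t", index=False)
    for channel in design["channel"]:
        df = matrices[channel]
        out = df.copy()
        out.index.name = "protein_id"
        out.to_csv(path / f"{channel}.tsv", sep="\t")
    return path


def read_matrix(file: str | Path) -> pd.DataFrame:
    """Parse one wide elution TSV with strict validation."""
    file = Path(file)
    with open(file, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise MatrixParseError(f"{file}: empty file") from None
        if not header or header[0] != "protein_id":
            raise MatrixParseError(
                f"{file}:1: first column must be 'protein_id', got "
                f"{header[0] if header else 'nothing'!r}"
            )
        frac_cols = header[1:]
        bad = [c for c in frac_cols if not c.startswith(FRACTION_PREFIX)]
        if bad:
            raise MatrixParseError(
                f"{file}:1: fraction columns must start with "
                f"'{FRACTION_PREFIX}', got {bad[0]!r}"
            )
        if len(set(frac_cols)) != len(frac_cols):
            raise MatrixParseError(f"{file}:1: duplicate fraction columns")
        ids: list[str] = []
        seen: set[str] = set()
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise MatrixParseError(
                    f"{file}:{lineno}: expected {len(header)} fields, "
                    f"found {len(row)}"
                )
            pid = row[0]
            if pid in seen:
                raise MatrixParseError(
                    f"{file}:{lineno}: duplicate protein id {pid!r}"
                )
            seen.add(pid)
            ids.append(pid)
            try:
                rows.append([float(v) for v in row[1:]])
            except ValueError as exc:
                raise MatrixParseError(f"{file}:{lineno}: {exc}") from None
    df = pd.DataFrame(np.asarray(rows, dtype=float), index=ids, columns=frac_cols)
    df.index.name = "protein_id"
    return df


def read_matrices(path: str | Path) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Round-trip counterpart of :func:`write_matrices`."""
    path = Path(path)
    design_file = path / DESIGN_FILE
    if not design_file.exists():
        raise MatrixParseError(f"{design_file}: missing channel design")
    design = pd.read_csv(design_file, sep="\t", dtype=str)
    required = {"channel", "condition", "replicate"}
    if not required <= set(design.columns):
        raise MatrixParseError(
            f"{design_file}: needs columns {sorted(required)}, "
            f"found {list(design.columns)}"
        )
    if design["channel"].duplicated().any():
        dup = design.loc[design["channel"].duplicated(), "channel"].iloc[0]
        raise MatrixParseError(f"{design_file}: duplicate channel {dup!r}")
    matrices: dict[str, pd.DataFrame] = {}
    universe: set[str] | None = None
    for channel in design["channel"]:
        df = read_matrix(path / f"{channel}.tsv")
        if universe is None:
            universe = set(df.index)
        elif set(df.index) != universe:
            raise MatrixParseError(
                f"{path / (channel + '.tsv')}: protein universe differs "
                "from previous channels"
            )
        matrices[channel] = df
    return matrices, design
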