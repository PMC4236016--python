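"""Reading, validating, scaling and writing expression matrices.

The on-disk contract is a plain UTF-8 CSV: the first record is a header
naming the conditions (time stamps or disease stages, e.g. ``K, E, L, BP``),
and every subsequent record is a gene name followed by one positive
expression signal per condition.  Gene and condition names must be unique;
file order is preserved everywhere downstream — no silent re-sorting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ExpressionError",
    "ExpressionParseError",
    "ExpressionValidationError",
    "read_expression_csv",
    "write_expression_csv",
    "scale_to_target_intensity",
]


class ExpressionError(ValueError):
    """Base class for expression-matrix input problems."""


class ExpressionParseError(ExpressionError):
    """Malformed CSV content (ragged row, non-numeric cell)."""


class ExpressionValidationError(ExpressionError):
    """Structurally valid file violating the matrix contract."""


def _check_unique(names: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for name in names:
        if name in seen:
            raise ExpressionValidationError(f"duplicate {kind} name: {name!r}")
        seen.add(name)


@dataclass(frozen=True)
class ExpressionMatrix:
    """An m-gene by t-condition matrix of positive expression signals.

    Parameters
    ----------
    gene_names
        Unique gene identifiers, one per row, in input order.
    condition_names
        Unique condition labels (time stamps / stages), one per column.
    values
        Strictly positive signal intensities, shape ``(m, t)``.
    """

    gene_names: tuple[str, ...]
    condition_names: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        object.__setattr__(self, "condition_names", tuple(self.condition_names))
        _check_unique(self.gene_names, "gene")
        _check_unique(self.condition_names, "condition")
        m, t = values.shape
        if len(self.gene_names) != m or len(self.condition_names) != t:
            raise ExpressionValidationError(
                f"shape {values.shape} does not match {len(self.gene_names)} genes "
                f"x {len(self.condition_names)} conditions"
            )
        if not np.all(np.isfinite(values)):
            raise ExpressionValidationError("non-finite expression values")
        if np.any(values <= 0):
            raise ExpressionValidationError(
                "expression values must be strictly positive (flooring is applied at read time)"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_names), columns=list(self.condition_names)
        )


def read_expression_csv(
    path: str | Path,
    *,
    floor: float = 1.0,
) -> ExpressionMatrix:
    """Read an expression matrix from the CSV contract.

    Values at or below zero (and empty cells) are floored at ``floor``
    signal units so the downstream log transform is defined; the count of
    floored cells is logged.  MAS5-style signals near zero are noise, so
    flooring loses nothing of biological interest.

    Raises
    ------
    ExpressionParseError
        Ragged row or non-numeric cell (reported with its line number).
    ExpressionValidationError
        Duplicate gene or condition names, or an empty matrix.
    """
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise ExpressionParseError(f"{path}: empty file")

    header = [c.strip() for c in lines[0].split(",")]
    condition_names = header[1:]
    if not condition_names:
        raise ExpressionParseError(f"{path}: header names no conditions")
    t = len(condition_names)

    gene_names: list[str] = []
    rows: list[list[float]] = []
    n_floored = 0
    for lineno, line in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in line.split(",")]
        if len(cells) != t + 1:
            raise ExpressionParseError(
                f"{path}:{lineno}: expected {t + 1} fields (gene + {t} values), got {len(cells)}"
            )
        gene_names.append(cells[0])
        row: list[float] = []
        for col, cell in enumerate(cells[1:], start=1):
            if cell == "":
                value = np.nan
            else:
                try:
                    value = float(cell)
                except ValueError:
                    raise ExpressionParseError(
                        f"{path}:{lineno}: non-numeric value {cell!r} in field {col + 1}"
                    ) from None
            if not np.isfinite(value) or value <= 0:
                value = floor
                n_floored += 1
            row.append(value)
        rows.append(row)

    if not rows:
        raise ExpressionValidationError(f"{path}: no data records")
    if n_floored:
        logger.info("%s: floored %d non-positive/missing cells to %g", path, n_floored, floor)
    return ExpressionMatrix(tuple(gene_names), tuple(condition_names), np.array(rows))


def write_expression_csv(x: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix back in the same CSV dialect (``Gene`` + conditions header)."""
    path = Path(path)
    frame = x.to_frame()
    frame.index.name = "Gene"
    # repr-round-trip float formatting keeps read(write(x)) bit-exact
    frame.to_csv(path, float_format=None)


def scale_to_target_intensity(
    x: ExpressionMatrix,
    target: float,
    *,
    trim: float = 0.0,
) -> ExpressionMatrix:
    """Scale every condition column to a common target mean intensity.

    This is the per-array global scaling step used to make chips
    comparable: each column is multiplied by ``target / mean(column)`` so
    that afterwards every column mean equals ``target``.  A trimmed-mean
    variant (``trim`` fraction removed from each tail, e.g. 0.02) is
    available; the default is the plain arithmetic mean.
    """
    if target <= 0:
        raise ValueError(f"target intensity must be positive, got {target}")
    if not 0 <= trim < 0.5:
        raise ValueError(f"trim fraction must be in [0, 0.5), got {trim}")
    if trim > 0:
        col_means = np.array(
            [stats.trim_mean(col, proportiontocut=trim) for col in x.values.T]
        )
    else:
        col_means = x.values.mean(axis=0)
    if np.any(col_means <= 0):
        bad = x.condition_names[int(np.argmax(col_means <= 0))]
        raise ExpressionValidationError(f"non-positive mean in condition {bad!r}")
    scaled = x.values * (target / col_means)
    return ExpressionMatrix(x.gene_names, x.condition_names, scaled)
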