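"""Accuracy, concordance and summary statistics for the simulation grid.

Prediction accuracy is the Pearson correlation between (G)EBVs and true
breeding values on the masked test set.  The impact of genotyping error on
the genomic relationship matrix is measured on the strict upper triangle
(the pairwise relationships) by Pearson's r and Lin's concordance
correlation coefficient

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)

with 1/n moment estimators, which penalizes both imprecision and
location/scale shifts.  Replicate summaries report mean +/- SE with
SE = sd / sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .relmat import RelationshipMatrix

__all__ = [
    "ConcordanceRecord",
    "accuracy",
    "standard_error",
    "lin_ccc",
    "grm_concordance",
    "aggregate",
]

RESULT_FACTORS = (
    "scenario",
    "h2",
    "replicate",
    "generation",
    "method",
    "panel_size",
    "error_rate",
)


@dataclass(frozen=True)
class ConcordanceRecord:
    """Agreement of an error-corrupted GRM with its error-free counterpart."""

    pearson_r: float
    lin_ccc: float
    n_pairs: int


def accuracy(tbv: np.ndarray, ebv: np.ndarray) -> float:
    """Pearson correlation of predicted with true breeding values."""
    tbv = np.asarray(tbv, dtype=np.float64)
    ebv = np.asarray(ebv, dtype=np.float64)
    if tbv.shape != ebv.shape or tbv.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if np.var(tbv) == 0.0 or np.var(ebv) == 0.0:
        raise ValueError("correlation undefined: zero variance input")
    return float(np.corrcoef(tbv, ebv)[0, 1])


def standard_error(replicate_values: np.ndarray) -> float:
    """SE of a replicate mean: sample standard deviation / sqrt(n)."""
    x = np.asarray(replicate_values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("standard error needs at least 2 replicates")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def lin_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (1/n moment estimators)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    vx = np.var(x)
    vy = np.var(y)
    if vx == 0.0 and vy == 0.0:
        raise ValueError("concordance undefined: both inputs are constant")
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2.0 * sxy / (vx + vy + (x.mean() - y.mean()) ** 2))


def grm_concordance(
    g_clean: RelationshipMatrix, g_err: RelationshipMatrix
) -> ConcordanceRecord:
    """Pearson r and Lin's CCC between the off-diagonals of two GRMs over the
    same individuals in the same order."""
    if g_clean.n != g_err.n or not np.array_equal(g_clean.ids, g_err.ids):
        raise ValueError("matrices cover different individuals")
    x = g_clean.offdiagonal()
    y = g_err.offdiagonal()
    return ConcordanceRecord(
        pearson_r=accuracy(x, y),
        lin_ccc=lin_ccc(x, y),
        n_pairs=x.size,
    )


def aggregate(
    records: pd.DataFrame,
    by: tuple[str, str],
    value: str = "accuracy",
) -> pd.DataFrame:
    """Two-way table of cell means and SEs, marginalizing everything else.

    Returns a long-format frame with columns ``by`` + (mean, se, n); cells
    with a single observation get a missing SE.
    """
    if records.empty:
        raise ValueError("no records to aggregate")
    for f in by:
        if f not in records.columns:
            raise KeyError(f"unknown factor {f!r}")
    if value not in records.columns:
        raise KeyError(f"unknown value column {value!r}")

    def _cell(x: pd.Series) -> pd.Series:
        return pd.Series(
            {
                "mean": x.mean(),
                "se": standard_error(x.to_numpy()) if x.size >= 2 else np.nan,
                "n": x.size,
            }
        )

    out = (
        records.groupby(list(by), dropna=False, observed=True)[value]
        .apply(_cell)
        .unstack()
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
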