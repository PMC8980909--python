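"""Covariate design-matrix construction shared by the screen and threshold models.

Covariates are referenced by cohort column name.  ``center`` expands to
indicator columns for every assessment center but the first observed
(reference) category; all other covariates enter as numeric columns.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["covariate_columns", "covariate_design", "complete_case_mask"]


def covariate_columns(
    table: pd.DataFrame, covariates: Sequence[str]
) -> list[tuple[str, np.ndarray]]:
    """Named covariate columns for a design matrix, without stacking.

    ``center`` expands to one indicator per non-reference assessment
    center; everything else enters as a numeric column.
    """
    out: list[tuple[str, np.ndarray]] = []
    for cov in covariates:
        if cov not in table.columns:
            raise KeyError(f"covariate column {cov!r} not in cohort table")
        if cov == "center":
            levels = np.sort(pd.unique(table[cov].dropna()))
            for level in levels[1:]:  # first level is the reference
                out.append(
                    (f"center_{level}", (table[cov].to_numpy() == level).astype(float))
                )
        else:
            out.append((cov, table[cov].to_numpy(dtype=float)))
    return out


def covariate_design(
    table: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Covariate block as a single matrix (one row per table row, no intercept)."""
    pairs = covariate_columns(table, covariates)
    if not pairs:
        return np.empty((len(table), 0)), []
    return np.column_stack([c for _, c in pairs]), [n for n, _ in pairs]


def complete_case_mask(table: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    """Boolean mask of rows with no missing value in any of ``columns``."""
    mask = np.ones(len(table), dtype=bool)
    for col in columns:
        mask &= table[col].notna().to_numpy()
    return mask
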