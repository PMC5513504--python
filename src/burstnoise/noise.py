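"""Group-corrected expression noise (CV) estimation and the technical-noise line.

The noise of a gene is its coefficient of variation across cells, with the
cell-to-cell deviations measured from each group's (embryo's, passage's) own
mean so that systematic between-group differences do not inflate the
estimate:

    CV = sqrt( sum_j sum_i (x_ij - xbar_j)^2 / (N - G) ) / xbar

where j indexes the G groups, N is the total cell count, and xbar is the
grand mean. With G = 1 this reduces to the ordinary sample CV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

__all__ = [
    "filter_detected",
    "group_corrected_sd",
    "noise_cv",
    "technical_noise_line",
    "mean_cv_regression",
]


def filter_detected(em: ExpressionMatrix) -> ExpressionMatrix:
    """Keep genes with expression > 0 in every cell."""
    keep = (em.values > 0).all(axis=1)
    if not keep.any():
        raise ValueError("no genes pass the detected-in-all-cells filter")
    return ExpressionMatrix(em.values.loc[keep], em.cell_group)


def group_corrected_sd(values: pd.DataFrame, cell_group: pd.Series) -> pd.Series:
    """Per-gene sd with deviations centered on each group's mean, df = N - G."""
    n_cells = values.shape[1]
    groups = cell_group.unique()
    n_groups = len(groups)
    if n_cells <= n_groups:
        raise ValueError(
            f"{n_cells} cells across {n_groups} groups leaves no degrees of freedom"
        )
    ss = np.zeros(values.shape[0])
    for g in groups:
        cols = cell_group.index[cell_group == g]
        sub = values[cols].to_numpy(float)
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return pd.Series(np.sqrt(ss / (n_cells - n_groups)), index=values.index)


def noise_cv(em: ExpressionMatrix, amplification: float | None = None) -> pd.DataFrame:
    """Per-gene mean and group-corrected CV; one row per gene.

    Returns a table with columns ``mean``, ``cv``, ``n_cells`` and, when an
    amplification factor is supplied, the technical CV at each gene's mean.
    """
    mean = em.values.mean(axis=1)
    if (mean == 0).any():
        bad = mean.index[mean == 0].tolist()
        raise ValueError(f"undefined CV (zero mean) for genes {bad[:5]}")
    sd = group_corrected_sd(em.values, em.cell_group)
    table = pd.DataFrame(
        {"mean": mean, "cv": sd / mean, "n_cells": em.n_cells}
    )
    if amplification is not None:
        table["cv_tech"] = technical_noise_line(amplification, mean.to_numpy())
    return table


def technical_noise_line(amplification: float, mean) -> np.ndarray:
    """Poisson-capture technical CV at a given mean: CV_tech = sqrt(A / mean).

    In log2 space this is the line with slope -0.5 and intercept
    0.5 * log2(A).
    """
    mean = np.asarray(mean, dtype=float)
    if amplification <= 0 or (mean <= 0).any():
        raise ValueError("amplification and mean must be positive")
    return np.sqrt(amplification / mean)


def mean_cv_regression(noise_table: pd.DataFrame, genes=None):
    """OLS of log2 CV on log2 mean; returns (slope, intercept, pearson_r).

    ``genes`` optionally restricts the fit to a gene subset.
    """
    sub = noise_table if genes is None else noise_table.loc[genes]
    if len(sub) < 3:
        raise ValueError("need at least 3 genes for the mean-CV regression")
    mu = sub["mean"].to_numpy(float)
    cv = sub["cv"].to_numpy(float)
    if (mu <= 0).any() or (cv <= 0).any():
        raise ValueError("mean-CV regression requires positive mean and CV")
    x, y = np.log2(mu), np.log2(cv)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        if np.ptp(x) == 0:
            raise ValueError("degenerate regression: log2 mean has zero variance")
        # constant CV: slope 0 by definition, correlation undefined -> 0
        return 0.0, float(y.mean()), 0.0
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)
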