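"""Two-color intrinsic-noise decomposition and gamma-fit burst frequency.

With two reporters (EGFP, dTomato) expressed from the same promoter in the
same cell, the between-channel disagreement isolates intrinsic noise:

    mu             = sqrt(mean(g) * mean(r))
    intrinsic CV^2 = mean((g - r)^2) / (2 * mean(g) * mean(r))

Burst frequency is the shape parameter alpha of a gamma distribution fitted
to the red-normalized green intensity (g / r per cell): in the burst model
the protein level is gamma distributed with shape = burst frequency and
scale = burst size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import TwoColorTable

__all__ = [
    "IntrinsicNoiseResult",
    "intrinsic_noise",
    "GammaFit",
    "fit_gamma",
    "StrainContrast",
    "compare_strains",
]


@dataclass(frozen=True)
class IntrinsicNoiseResult:
    reporter: str
    strain: str
    replicate: object
    mu: float
    intrinsic_cv2: float
    n: int

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.intrinsic_cv2 < 0:
            raise ValueError("intrinsic CV^2 must be non-negative")


def intrinsic_noise(
    table: TwoColorTable, normalization: str | None = "mean"
) -> IntrinsicNoiseResult:
    """Intrinsic noise from paired two-color intensities.

    ``normalization="mean"`` divides each channel by its own mean (making the
    result unit-free); ``None`` uses the raw arbitrary units.
    """
    g, r = table.g, table.r
    if len(g) < 2:
        raise ValueError("need at least 2 cells")
    if normalization == "mean":
        g = g / g.mean()
        r = r / r.mean()
    elif normalization is not None:
        raise ValueError(f"unknown normalization {normalization!r}")
    if (g <= 0).any() or (r <= 0).any():
        raise ValueError("non-positive intensities after normalization")
    gbar, rbar = g.mean(), r.mean()
    cv2 = float(np.mean((g - r) ** 2) / (2.0 * gbar * rbar))
    first = table.table.iloc[0]
    return IntrinsicNoiseResult(
        reporter=str(first["reporter"]),
        strain=str(first["strain"]),
        replicate=first["replicate"],
        mu=float(np.sqrt(gbar * rbar)),
        intrinsic_cv2=cv2,
        n=len(g),
    )


@dataclass(frozen=True)
class GammaFit:
    alpha: float
    beta: float  # rate
    loglik: float
    burst_frequency: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("gamma parameters must be positive")


def _moment_init(x: np.ndarray) -> tuple[float, float]:
    m, v = x.mean(), x.var()
    return m * m / v, m / v  # shape, rate


def fit_gamma(data, normalize_by_red: bool = True) -> GammaFit:
    """Maximum-likelihood gamma fit; burst frequency = fitted shape alpha.

    ``data`` is a TwoColorTable (per-cell value g/r, or g when
    ``normalize_by_red`` is False) or a 1-D array of positive values.
    Moment matching initializes the optimizer and serves as the fallback if
    the MLE does not converge.
    """
    if isinstance(data, TwoColorTable):
        x = data.g / data.r if normalize_by_red else data.g
    else:
        x = np.asarray(data, dtype=float)
    if (x <= 0).any():
        raise ValueError("gamma fit requires strictly positive values")
    if x.var() == 0:
        raise ValueError("degenerate input: zero variance")
    a0, rate0 = _moment_init(x)
    try:
        shape, _, scale = stats.gamma.fit(x, a0, floc=0, scale=1.0 / rate0)
        if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
            raise ValueError("non-finite MLE")
    except Exception:
        shape, scale = a0, 1.0 / rate0
    loglik = float(np.sum(stats.gamma.logpdf(x, shape, scale=scale)))
    return GammaFit(
        alpha=float(shape), beta=float(1.0 / scale), loglik=loglik,
        burst_frequency=float(shape),
    )


@dataclass(frozen=True)
class StrainContrast:
    """Per-genotype noise-vs-level slopes and the interaction test."""

    slopes: dict
    intercepts: dict
    slope_difference: float
    interaction_p: float


def compare_strains(results: dict[str, list[IntrinsicNoiseResult]]) -> StrainContrast:
    """Contrast the log2 intrinsic CV vs log2 mu regression between genotypes.

    Fits a joint OLS with a genotype x log2(mu) interaction; the interaction
    p-value tests whether one genotype's regression is flatter.
    """
    import statsmodels.api as sm

    if len(results) != 2:
        raise ValueError("compare_strains contrasts exactly two genotypes")
    rows = []
    for genotype, items in results.items():
        for res in items:
            rows.append((genotype, np.log2(res.mu), np.log2(np.sqrt(res.intrinsic_cv2))))
    df = pd.DataFrame(rows, columns=["genotype", "log2_mu", "log2_cv"])
    genotypes = sorted(results)
    for gt in genotypes:
        if (df["genotype"] == gt).sum() < 3:
            raise ValueError(f"genotype {gt!r} has fewer than 3 points; cannot fit a slope")
    is_second = (df["genotype"] == genotypes[1]).astype(float)
    X = sm.add_constant(
        np.column_stack([df["log2_mu"], is_second, df["log2_mu"] * is_second])
    )
    fit = sm.OLS(df["log2_cv"].to_numpy(), X).fit()
    params = np.asarray(fit.params)
    slope0 = float(params[1])
    slope_diff = float(params[3])
    slopes = {genotypes[0]: slope0, genotypes[1]: slope0 + slope_diff}
    intercepts = {
        genotypes[0]: float(params[0]),
        genotypes[1]: float(params[0] + params[2]),
    }
    return StrainContrast(
        slopes=slopes,
        intercepts=intercepts,
        slope_difference=slope_diff,
        interaction_p=float(np.asarray(fit.pvalues)[3]),
    )
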