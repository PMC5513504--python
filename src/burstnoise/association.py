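"""Statistics linking histone-mark intensities to burst parameters,
expression level, and noise.

The central statistic is the contrast D = |r_a| - |r_b| between a mark's
correlation with two paired gene-level targets (burst frequency vs burst
size, or noise vs mean). Its significance comes from a permutation test that
shuffles the mark intensities across genes while keeping the target pair
intact. The module also provides expression-noise axis grouping, usage-
preference enrichment, Mantel-Haenszel stratified odds ratios over
expression bins, rank-based partial correlations, and the expression-matched
relative intensity ratio used for pathway comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from statsmodels.stats.contingency_tables import StratifiedTable

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "paired_correlation",
    "permutation_test",
    "partial_correlation",
    "axis_groups",
    "usage_preference",
    "StratifiedOR",
    "mh_common_or",
    "mh_common_or_from_tables",
    "relative_intensity_ratio",
    "two_group_noise_test",
]


@dataclass(frozen=True)
class AssociationResult:
    """Paired correlations of one mark with two targets and their contrast."""

    mark: str
    r_a: float
    r_b: float
    d: float  # |r_a| - |r_b|
    p: float | None
    method: str
    n: int


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def _check_vectors(intensity, target_a, target_b):
    x = np.asarray(intensity, dtype=float)
    a = np.asarray(target_a, dtype=float)
    b = np.asarray(target_b, dtype=float)
    if not (len(x) == len(a) == len(b)):
        raise ValueError("vectors must be aligned over the same genes")
    if len(x) < 3:
        raise ValueError("need at least 3 genes")
    for name, v in (("intensity", x), ("target_a", a), ("target_b", b)):
        if np.ptp(v) == 0:
            raise ValueError(f"correlation undefined: {name} has zero variance")
    return x, a, b


def paired_correlation(
    intensity, target_a, target_b, method: str = "spearman", mark: str = "mark"
) -> AssociationResult:
    """r_a, r_b of a mark against two paired targets and D = |r_a| - |r_b|."""
    x, a, b = _check_vectors(intensity, target_a, target_b)
    r_a = _corr(x, a, method)
    r_b = _corr(x, b, method)
    return AssociationResult(
        mark=mark, r_a=r_a, r_b=r_b, d=abs(r_a) - abs(r_b), p=None,
        method=method, n=len(x),
    )


def permutation_test(
    intensity,
    target_a,
    target_b,
    method: str = "spearman",
    n_perm: int = 1000,
    seed: int = 0,
    mark: str = "mark",
) -> AssociationResult:
    """Two-tailed permutation p for D = |r_a| - |r_b|.

    The intensity vector is shuffled across genes (the target pair stays
    intact), D recomputed each round, and p = (1 + #{|D_perm| >= |D_obs|}) /
    (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x, a, b = _check_vectors(intensity, target_a, target_b)
    obs = paired_correlation(x, a, b, method, mark)

    if method == "spearman":
        x_t = stats.rankdata(x)
        a_t = stats.rankdata(a)
        b_t = stats.rankdata(b)
    else:
        x_t, a_t, b_t = x, a, b
    # permuted Pearson correlations in one matrix product: shuffling ranks
    # and correlating is exactly the permuted Spearman correlation
    rng = np.random.default_rng(seed)
    n = len(x_t)
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    xp = (x_t[perm_idx] - x_t.mean()) / x_t.std()
    az = (a_t - a_t.mean()) / a_t.std()
    bz = (b_t - b_t.mean()) / b_t.std()
    d_perm = np.abs(xp @ az / n) - np.abs(xp @ bz / n)
    n_extreme = int(np.sum(np.abs(d_perm) >= abs(obs.d)))
    p = (1 + n_extreme) / (n_perm + 1)
    return AssociationResult(
        mark=mark, r_a=obs.r_a, r_b=obs.r_b, d=obs.d, p=p, method=method, n=n
    )


def _residualize(y: np.ndarray, controls: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(y)), controls])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def partial_correlation(x, y, controls) -> float:
    """Rank-based (Spearman-type) partial correlation of x and y given controls.

    All variables are rank-transformed, the controls are regressed out of
    both focal variables, and the Pearson correlation of the residuals is
    returned.
    """
    x = stats.rankdata(np.asarray(x, dtype=float))
    y = stats.rankdata(np.asarray(y, dtype=float))
    c = np.asarray(controls, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    c = np.column_stack([stats.rankdata(c[:, j]) for j in range(c.shape[1])])
    rx = _residualize(x, c)
    ry = _residualize(y, c)
    # residual variance at floating-point noise level means the focal
    # variable is fully explained by the controls
    tol = 1e-10 * len(x)
    if rx.std() <= tol or ry.std() <= tol:
        return 0.0
    return float(stats.pearsonr(rx, ry).statistic)


# ---------------------------------------------------------------------------
# major/minor-axis grouping of the mean-noise scatter


def _principal_axes(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Major/minor axes of centered 2-D data, deterministically oriented.

    The major axis points toward increasing expression (positive first
    coordinate); the minor axis toward increasing noise (positive second
    coordinate).
    """
    cov = np.cov(z.T)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)  # stable under tied eigenvalues
    major = v[:, order[-1]]
    minor = v[:, order[0]]
    if major[0] < 0 or (major[0] == 0 and major[1] < 0):
        major = -major
    if minor[1] < 0 or (minor[1] == 0 and minor[0] < 0):
        minor = -minor
    return major, minor


def axis_groups(
    noise_table: pd.DataFrame,
    confidence: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Divide genes into 4 groups by the major/minor axes of (log2 mean, log2 CV).

    Groups: 1 high-expression-high-noise, 2 high-expression-low-noise,
    3 low-expression-high-noise, 4 low-expression-low-noise. Expression
    high/low is the side of the minor axis (projection on the major axis);
    noise high/low given expression is the side of the major axis
    (projection on the minor axis). Genes exactly on an axis go to the low
    side. With ``confidence=True`` a gene is flagged confident when its
    bootstrap 95% band of signed distances to both axes excludes zero.
    """
    if len(noise_table) < 10:
        raise ValueError("need at least 10 genes to fit the axes")
    X = np.column_stack(
        [np.log2(noise_table["mean"].to_numpy(float)),
         np.log2(noise_table["cv"].to_numpy(float))]
    )
    spread = X.std(axis=0)
    spread[spread == 0] = 1.0  # a flat coordinate stays flat after centering
    z = (X - X.mean(axis=0)) / spread
    major, minor = _principal_axes(z)
    expr_score = z @ major  # signed distance to the minor axis
    noise_score = z @ minor  # signed distance to the major axis
    high_expr = expr_score > 0
    high_noise = noise_score > 0
    group = np.select(
        [high_expr & high_noise, high_expr & ~high_noise,
         ~high_expr & high_noise],
        [1, 2, 3],
        default=4,
    )
    out = pd.DataFrame(
        {
            "group": group,
            "major_side": np.where(high_noise, "high_noise", "low_noise"),
            "minor_side": np.where(high_expr, "high_expr", "low_expr"),
        },
        index=noise_table.index,
    )
    if confidence:
        rng = np.random.default_rng(seed)
        n = len(z)
        expr_boot = np.empty((n_boot, n))
        noise_boot = np.empty((n_boot, n))
        for k in range(n_boot):
            zb = z[rng.integers(0, n, n)]
            center = zb.mean(axis=0)
            major_b, minor_b = _principal_axes(zb - center)
            expr_boot[k] = (z - center) @ major_b
            noise_boot[k] = (z - center) @ minor_b
        lo_e, hi_e = np.percentile(expr_boot, [2.5, 97.5], axis=0)
        lo_n, hi_n = np.percentile(noise_boot, [2.5, 97.5], axis=0)
        out["confident"] = ((lo_e > 0) | (hi_e < 0)) & ((lo_n > 0) | (hi_n < 0))
    return out


def usage_preference(
    groups: pd.Series, intensity: pd.DataFrame
) -> pd.DataFrame:
    """High/low-intensity enrichment of each mark within each gene group.

    Each mark is split at its median over all genes (ties go to "low");
    per (mark, group) the table reports high/low counts, their ratio (inf
    when no lows), and the hypergeometric p for over-representation of
    high-intensity genes in the group against the background of all other
    groups.
    """
    common = groups.index.intersection(intensity.index)
    groups = groups.loc[common]
    rows = []
    for mark in intensity.columns:
        vals = intensity.loc[common, mark].astype(float)
        high = vals > vals.median()
        m_total = len(common)
        n_high_total = int(high.sum())
        for grp in sorted(groups.unique()):
            in_grp = groups == grp
            n_grp = int(in_grp.sum())
            k_high = int((high & in_grp).sum())
            k_low = n_grp - k_high
            ratio = k_high / k_low if k_low else float("inf")
            p = float(stats.hypergeom.sf(k_high - 1, m_total, n_high_total, n_grp))
            rows.append((mark, grp, k_high, k_low, ratio, p))
    return pd.DataFrame(
        rows, columns=["mark", "group", "n_high", "n_low", "ratio", "p"]
    )


# ---------------------------------------------------------------------------
# Mantel-Haenszel stratified odds ratio


@dataclass
class StratifiedOR:
    """Per-stratum 2x2 tables with the MH common OR and its 95% CI."""

    tables: list[np.ndarray]
    common_or: float
    ci_low: float
    ci_high: float
    n_strata_used: int


def _mh_from_tables(tables: list[np.ndarray], alpha: float = 0.05) -> StratifiedOR:
    usable = []
    for t in tables:
        t = np.asarray(t, dtype=float)
        if t.shape != (2, 2) or (t < 0).any():
            raise ValueError("each stratum must be a non-negative 2x2 table")
        # a stratum with an empty margin contributes nothing to the MH sums
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            logger.info("dropping stratum with an empty margin: %s", t.tolist())
            continue
        usable.append(t)
    if not usable:
        raise ValueError("no usable strata for the Mantel-Haenszel estimate")
    st = StratifiedTable([t for t in usable])
    or_mh = float(st.oddsratio_pooled)
    lo, hi = st.oddsratio_pooled_confint(alpha=alpha)
    return StratifiedOR(
        tables=usable, common_or=or_mh, ci_low=float(lo), ci_high=float(hi),
        n_strata_used=len(usable),
    )


def mh_common_or(
    gene_table: pd.DataFrame,
    n_bins: int = 10,
    alpha: float = 0.05,
) -> StratifiedOR:
    """MH common odds ratio for high mark intensity vs dosage sensitivity,
    stratified by expression bins.

    ``gene_table`` needs columns ``sensitive`` (bool), ``intensity``, and
    ``expression``. Genes are cut into ``n_bins`` equal-sized expression
    bins (ties broken by stable gene order); within each bin the intensity
    is median-split (ties to low) and the 2x2 table [[high&sensitive,
    high&insensitive], [low&sensitive, low&insensitive]] is formed. The
    common OR is Sum(a_i d_i / n_i) / Sum(b_i c_i / n_i) with a
    Robins-Breslow-Greenland 95% CI.
    """
    required = {"sensitive", "intensity", "expression"}
    if not required.issubset(gene_table.columns):
        raise ValueError(f"gene table missing columns {required - set(gene_table.columns)}")
    df = gene_table.copy()
    order = stats.rankdata(df["expression"].to_numpy(float), method="ordinal")
    df["_bin"] = pd.qcut(order, n_bins, labels=False)
    tables = []
    for _, sub in df.groupby("_bin", sort=True):
        high = sub["intensity"].astype(float) > sub["intensity"].astype(float).median()
        sens = sub["sensitive"].astype(bool)
        tables.append(
            np.array(
                [[int((high & sens).sum()), int((high & ~sens).sum())],
                 [int((~high & sens).sum()), int((~high & ~sens).sum())]]
            )
        )
    return _mh_from_tables(tables, alpha=alpha)


def mh_common_or_from_tables(tables, alpha: float = 0.05) -> StratifiedOR:
    """MH common OR directly from pre-built 2x2 stratum tables."""
    return _mh_from_tables([np.asarray(t) for t in tables], alpha=alpha)


# ---------------------------------------------------------------------------
# expression-matched relative intensity ratio


def relative_intensity_ratio(
    pathway_genes,
    numerator: pd.Series,
    denominator: pd.Series,
    expression: pd.Series,
    control_genes,
    n_controls: int = 100,
) -> pd.Series:
    """Per-gene mark-intensity ratio relative to expression-matched controls.

    For each pathway gene the numerator/denominator intensity ratio is
    divided by the median ratio of the ``n_controls`` control-group genes
    nearest in |delta log2 expression|. Genes with zero denominator
    intensity are excluded (logged).
    """
    control_genes = [g for g in control_genes if denominator.get(g, 0) > 0]
    if not control_genes:
        raise ValueError("control group is empty after removing zero-denominator genes")
    if len(control_genes) < n_controls:
        logger.warning(
            "control group has %d genes < n_controls=%d; using all",
            len(control_genes), n_controls,
        )
    ctrl_expr = np.log2(expression.loc[control_genes].to_numpy(float))
    ctrl_ratio = (
        numerator.loc[control_genes] / denominator.loc[control_genes]
    ).to_numpy(float)
    out = {}
    for gene in pathway_genes:
        den = denominator.get(gene, 0.0)
        if den <= 0:
            logger.info("excluding %s: zero denominator intensity", gene)
            continue
        ratio = numerator[gene] / den
        dist = np.abs(ctrl_expr - np.log2(float(expression[gene])))
        nearest = np.argsort(dist, kind="stable")[:n_controls]
        out[gene] = ratio / float(np.median(ctrl_ratio[nearest]))
    return pd.Series(out, name="relative_ratio")


def two_group_noise_test(cv: pd.Series, label: pd.Series) -> tuple[float, float]:
    """Welch t test on log2 CV between the two label classes; returns (t, p)."""
    label = label.astype(bool)
    a = np.log2(cv[label].to_numpy(float))
    b = np.log2(cv[~label].to_numpy(float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both label classes must be non-empty")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
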