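"""Synthetic data with the statistical structure the analysis assumes.

The generator implements the burst-like transcription model: each gene fires
transcriptional bursts at frequency f (per mRNA lifetime) producing a
geometrically distributed number of transcripts with mean burst size b, so
that steady-state mRNA counts are negative binomial with mean f*b and Fano
factor 1 + b. On top of the latent counts it layers a multiplicative
log-normal embryo (group) effect, per-molecule binomial capture, and an
RPKM-like global rescaling anchored to the total mRNA content of a typical
mammalian cell (200,000 molecules).

Histone-mark peaks, two-color fluorescence, and MNase midpoint tracks are
generated with tunable coupling to the planted burst parameters so every
downstream statistic can be tested against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneAnnotation, MidpointTrack, PeakSet, TwoColorTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "MarkCoupling",
    "simulate_counts",
    "simulate_marks",
    "simulate_two_color",
    "simulate_midpoints",
    "make_annotation",
    "default_mark_couplings",
]

PROMOTER_UPSTREAM = 2000  # bp upstream of TSS rendered as the promoter window


@dataclass(frozen=True)
class MarkCoupling:
    """How one simulated histone mark tracks a burst parameter.

    target: which per-gene quantity the mark intensity follows
        ("burst_frequency", "burst_size", "expression_level", or "none").
    rho: coupling strength on z-scored log target (Pearson scale).
    noise_sd: sd of the additive Gaussian noise; default sqrt(1 - rho^2) so
        the planted correlation with the log target is exactly rho.
    localization: "promoter" (peak in TSS-2kb..TSS) or "gene_body" (TSS..TES).
    """

    target: str = "none"
    rho: float = 0.0
    noise_sd: float | None = None
    localization: str = "gene_body"

    def __post_init__(self) -> None:
        if self.target not in {"burst_frequency", "burst_size", "expression_level", "none"}:
            raise ValueError(f"unknown coupling target {self.target!r}")
        if self.localization not in {"promoter", "gene_body"}:
            raise ValueError(f"unknown localization {self.localization!r}")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("coupling rho must lie in [-1, 1]")


def default_mark_couplings() -> dict[str, MarkCoupling]:
    """Two exemplar marks: a frequency-coupled gene-body mark (H3K79me2-like)
    and a level-coupled promoter mark (H3K4me3-like)."""
    return {
        "H3K79me2": MarkCoupling("burst_frequency", 0.6, localization="gene_body"),
        "H3K4me3": MarkCoupling("expression_level", 0.6, localization="promoter"),
    }


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the count simulation.

    Defaults follow the desk-scale study design: 5,000 genes, 200 cells in a
    single group, burst frequency log-uniform over two decades, burst size
    log-uniform over two decades, no capture loss, no embryo effect, and a
    200,000-molecule transcriptome.
    """

    n_genes: int = 5000
    groups: tuple[tuple[str, int], ...] = (("E1", 200),)
    burst_frequency_range: tuple[float, float] = (0.5, 50.0)
    burst_size_range: tuple[float, float] = (1.0, 100.0)
    fixed_burst_size: float = 4.0
    fixed_burst_frequency: float = 10.0
    regulation_mode: str = "mixed"  # frequency-only | size-only | mixed
    capture_efficiency: float = 1.0
    embryo_effect_sd: float = 0.0
    amplification: float = 2.75
    total_mrna_per_cell: float = 200_000.0
    match_total_mrna: bool = True
    mark_coupling: dict[str, MarkCoupling] = field(default_factory=default_mark_couplings)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regulation_mode not in {"frequency-only", "size-only", "mixed"}:
            raise ValueError(f"unknown regulation_mode {self.regulation_mode!r}")
        if not 0.0 < self.capture_efficiency <= 1.0:
            raise ValueError("capture_efficiency must lie in (0, 1]")
        for lo, hi in (self.burst_frequency_range, self.burst_size_range):
            if lo <= 0 or hi < lo:
                raise ValueError("rate ranges must be positive and ordered")
        if self.fixed_burst_size < 0 or self.fixed_burst_frequency <= 0:
            raise ValueError("fixed burst parameters must be non-negative / positive")
        if self.embryo_effect_sd < 0:
            raise ValueError("embryo_effect_sd must be >= 0")

    @property
    def n_cells(self) -> int:
        return sum(n for _, n in self.groups)


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset; never consumed by the pipeline."""

    genes: pd.DataFrame  # index gene_id; burst_frequency, burst_size, mean
    embryo_factor: pd.Series  # per cell
    scale: float  # counts -> RPKM-like units
    mark_intensity: pd.DataFrame | None = None  # gene x mark, filled by simulate_marks


def _loguniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), n))


def simulate_counts(config: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate an RPKM-like expression matrix under the burst model.

    Latent per-cell counts are negative binomial with mean f*b*e_c and Fano
    1 + b (e_c the cell's multiplicative log-normal embryo factor with unit
    mean); observed counts are binomially thinned at the capture efficiency;
    the reported matrix is the observed counts under a single global scale
    chosen so the average column sum equals total_mrna_per_cell x
    amplification.
    """
    rng = np.random.default_rng(config.seed)
    g = config.n_genes

    if config.regulation_mode == "frequency-only":
        f = _loguniform(rng, *config.burst_frequency_range, g)
        b = np.full(g, config.fixed_burst_size)
    elif config.regulation_mode == "size-only":
        f = np.full(g, config.fixed_burst_frequency)
        b = _loguniform(rng, *config.burst_size_range, g)
    else:
        f = _loguniform(rng, *config.burst_frequency_range, g)
        b = _loguniform(rng, *config.burst_size_range, g)

    # b is Fano - 1; b = 0 means every burst delivers exactly one molecule
    # (Poisson limit), so the per-gene mean is f * max(b, 1)
    eff_b = np.where(b > 0, b, 1.0)

    if config.match_total_mrna:
        # anchor the expected transcriptome size to the configured total so
        # the RPKM -> count calibration downstream is self-consistent
        f = f * config.total_mrna_per_cell / float(np.sum(f * eff_b))

    gene_ids = pd.Index([f"G{i:05d}" for i in range(g)], name="gene_id")
    cell_ids, group_labels = [], []
    for label, n in config.groups:
        cell_ids += [f"{label}_c{i}" for i in range(n)]
        group_labels += [label] * n
    n_cells = len(cell_ids)

    if config.embryo_effect_sd > 0:
        sd = config.embryo_effect_sd
        per_group = {lab: np.exp(rng.normal(-0.5 * sd**2, sd)) for lab, _ in config.groups}
        e = np.array([per_group[lab] for lab in group_labels])
    else:
        e = np.ones(n_cells)

    mean = f[:, None] * eff_b[:, None] * e[None, :]
    latent = np.empty(mean.shape, dtype=np.int64)
    bursty = b > 0  # b = 0 is the Poisson limit (bursts of a single molecule)
    if bursty.any():
        bcol = b[bursty, None]
        latent[bursty] = rng.negative_binomial(
            mean[bursty] / bcol, 1.0 / (1.0 + bcol)
        )
    if (~bursty).any():
        latent[~bursty] = rng.poisson(mean[~bursty])

    p = config.capture_efficiency
    observed = latent if p >= 1.0 else rng.binomial(latent, p)

    target_colsum = config.total_mrna_per_cell * config.amplification
    mean_colsum = observed.sum(axis=0).mean()
    if mean_colsum == 0:
        raise ValueError("all simulated counts are zero; increase rates")
    scale = target_colsum / mean_colsum
    values = pd.DataFrame(observed * scale, index=gene_ids, columns=cell_ids)

    detected = (observed > 0).all(axis=1)
    truth_genes = pd.DataFrame(
        {"burst_frequency": f, "burst_size": b, "mean": f * eff_b,
         "detected_in_all_cells": detected},
        index=gene_ids,
    )
    truth = SimTruth(
        genes=truth_genes,
        embryo_factor=pd.Series(e, index=cell_ids),
        scale=scale,
    )
    em = ExpressionMatrix(values, pd.Series(group_labels, index=cell_ids))
    return em, truth


def make_annotation(
    gene_ids,
    gene_length: int = 5000,
    spacing: int = 10_000,
    chrom: str = "chrSim",
    seed: int = 0,
) -> GeneAnnotation:
    """Lay simulated genes head-to-tail on one chromosome, random strand."""
    rng = np.random.default_rng(seed)
    gene_ids = pd.Index(gene_ids, name="gene_id")
    n = len(gene_ids)
    starts = PROMOTER_UPSTREAM + spacing * np.arange(n)
    ends = starts + gene_length
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    tss = np.where(strand == "+", starts, ends)
    tes = np.where(strand == "+", ends, starts)
    table = pd.DataFrame(
        {"chrom": chrom, "tss": tss, "tes": tes, "strand": strand}, index=gene_ids
    )
    return GeneAnnotation(table)


def simulate_marks(
    truth: SimTruth,
    config: SimConfig,
    annotation: GeneAnnotation,
    seed: int | None = None,
) -> dict[str, PeakSet]:
    """Render per-mark peak sets whose scored intensity follows the coupling.

    The per-gene target intensity is rho * z(log target) + noise, shifted to
    be positive, and written as the signalValue of a single peak placed in
    the promoter window (promoter marks) or across the gene body (gene-body
    marks) -- so union-normalized scoring recovers the target exactly.
    Records the planted intensities in ``truth.mark_intensity``.
    """
    missing = truth.genes.index.difference(annotation.gene_ids)
    if len(missing):
        raise ValueError(f"annotation does not cover simulated genes: {missing[:5].tolist()}")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    target_map = {
        "burst_frequency": truth.genes["burst_frequency"],
        "burst_size": truth.genes["burst_size"],
        "expression_level": truth.genes["mean"],
    }
    ann = annotation.table.loc[truth.genes.index]
    peaksets: dict[str, PeakSet] = {}
    intensities: dict[str, pd.Series] = {}
    for mark, coupling in config.mark_coupling.items():
        n = len(truth.genes)
        noise_sd = (
            np.sqrt(max(0.0, 1.0 - coupling.rho**2))
            if coupling.noise_sd is None
            else coupling.noise_sd
        )
        if coupling.target == "none":
            y = rng.normal(0.0, 1.0, n)
        else:
            t = np.log(target_map[coupling.target].to_numpy(float))
            z = (t - t.mean()) / t.std()
            y = coupling.rho * z + rng.normal(0.0, noise_sd, n)
        intensity = y - y.min() + 0.1  # positive, Pearson-preserving shift
        intensities[mark] = pd.Series(intensity, index=truth.genes.index)

        plus = (ann["strand"] == "+").to_numpy()
        tss = ann["tss"].to_numpy()
        tes = ann["tes"].to_numpy()
        if coupling.localization == "promoter":
            start = np.where(plus, tss - PROMOTER_UPSTREAM, tss)
            end = np.where(plus, tss, tss + PROMOTER_UPSTREAM)
        else:
            start = np.where(plus, tss, tes)
            end = np.where(plus, tes, tss)
        start = np.maximum(start, 0)
        table = pd.DataFrame(
            {"chrom": ann["chrom"].to_numpy(), "start": start.astype(int),
             "end": end.astype(int), "signal": intensity}
        )
        peaksets[mark] = PeakSet(table)
    truth.mark_intensity = pd.DataFrame(intensities)
    return peaksets


def simulate_two_color(
    n_cells: int = 40_000,
    alpha: float = 4.0,
    beta: float = 1.0,
    extrinsic_sd: float = 0.0,
    seed: int = 0,
    strain: str = "WT",
    reporter: str = "reporter",
    replicate: int = 1,
) -> TwoColorTable:
    """Two reporters driven by the same promoter in the same cell.

    Each channel is an independent Gamma(alpha, rate beta) draw scaled by a
    shared per-cell log-normal extrinsic factor (unit mean), so the intrinsic
    CV^2 is 1/alpha in the large-n limit regardless of the extrinsic spread.
    """
    rng = np.random.default_rng(seed)
    if extrinsic_sd > 0:
        extr = np.exp(rng.normal(-0.5 * extrinsic_sd**2, extrinsic_sd, n_cells))
    else:
        extr = np.ones(n_cells)
    g = extr * rng.gamma(alpha, 1.0 / beta, n_cells)
    r = extr * rng.gamma(alpha, 1.0 / beta, n_cells)
    table = pd.DataFrame(
        {"cell": [f"cell{i}" for i in range(n_cells)], "g": g, "r": r,
         "strain": strain, "reporter": reporter, "replicate": replicate}
    )
    return TwoColorTable(table)


def simulate_midpoints(
    n_genes: int,
    occupancy_profile,
    seed: int = 0,
    gene_ids=None,
) -> MidpointTrack:
    """Poisson midpoint counts around a shared positional intensity profile.

    ``occupancy_profile[i]`` is the expected midpoint count i+1 bases
    upstream of the TSS.
    """
    rng = np.random.default_rng(seed)
    lam = np.asarray(occupancy_profile, dtype=float)
    if (lam < 0).any():
        raise ValueError("occupancy profile must be non-negative")
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    counts = {gid: rng.poisson(lam) for gid in gene_ids}
    return MidpointTrack(counts)
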