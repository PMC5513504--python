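# Methods

## Noise estimation

Expression noise is the coefficient of variation of a gene's expression
across cells. Cells from early embryos (or culture passages) carry shared,
group-level expression shifts, so deviations are measured from each group's
own mean while the denominator uses the grand mean:

CV = sqrt( Σ_j Σ_i (x_ij − x̄_j)² / (N − G) ) / ( Σ_j Σ_i x_ij / N )

with `G` groups and `N` cells in total; the degrees of freedom are `N − G`
(one mean per group), so `G = 1` reduces to the ordinary sample CV. The
correction removes additive group offsets exactly; for the multiplicative
group effects the simulator plants, it removes most (not all) of the
between-group component, which is what the corresponding property test
asserts. Genes are filtered to those detected (value > 0) in every cell
*before* CV computation, because sampling error dominates lowly expressed
genes; the technical floor under a Poisson-capture model is
`CV_tech = sqrt(A/μ)` — a line of slope −0.5 and intercept `0.5·log2(A)` in
log2–log2 space. All mean–noise regressions operate on log2 values.

## Burst-parameter inference

Steady-state counts under burst-like transcription (bursts at frequency
`f`, geometric burst sizes with mean `b`) are negative binomial with
mean `f·b/γ` and Fano factor `1 + b`. Hence `burst size = σ²/μ − 1` and
`burst frequency = μ·γ / burst size`. Two calibrations matter:

- **Amplification factor.** Sequencing units (RPKM-like) are proportional
  to, not equal to, molecule counts; the Fano factor is not scale
  invariant. `A = RPKM_total / total mRNA per cell` (200,000 for a typical
  mammalian cell) converts units to counts via `N_i = RPKM_i / A`.
  RPKM_total is the summed per-gene mean over *all* genes of the
  experiment; computing it after the detection filter biases `A` low and
  inflates every burst size (about 15% in our simulations), so
  `estimate_bursts_mrna` accepts an amplification factor computed
  pre-filter.
- **Decay rate.** `γ` defaults to 1 min⁻¹ (frequency per mRNA lifetime); a
  per-gene decay table can be supplied, and genes without an entry get NaN
  frequency rather than an imputed value.

The variance uses the same group-centered sum of squares as the noise
estimator when a group map is available (flag to disable). Genes with
Fano ≤ 1 have no defined burst size and are excluded rather than clamped;
the default presentation cutoff keeps burst size > 0.75 (strictly), with
0.5 and 1.0 as sensitivity variants. Protein-mode inference is identical
after normalizing arbitrary fluorescence units to counts against the total
protein content of a yeast cell (5×10⁷), with `γ_p` per gene; it assumes
mRNA turnover is much faster than protein turnover.

## Histone-mark scoring and metaprofiles

A gene's range runs from 2 kb upstream of the TSS (strand-relative) to the
TES, clipped at position 0. Peaks overlapping the range are clipped to it;
with clipped lengths `L_i` and signal values `E_i` the intensity is
`Σ L_i·E_i / L`, where `L` is the full range length (`gene_length`
variant) or the length of the union of the clipped peaks
(`peak_covered_length` variant, the default — it does not dilute marks
confined to part of a gene). Consequences asserted as invariants: the
union variant dominates the gene-length variant, both are invariant to
splitting a peak, and both equal `E` for a single peak covering the whole
range. broadPeak input uses column 7 (signalValue) as `E_i`; the score
column is ignored. Coordinates are zero-based half-open internally;
1-based inclusive annotation files are converted at the boundary.

TSS metaprofiles average, per strand-relative bin (default −2000..+4000 in
100-bp bins), the coverage-weighted signal over genes. A mark is called
promoter-localized when more than half its profile mass lies below the
+500 bp offset (both numbers configurable) — a reproducible stand-in for a
by-eye classification. Promoter nucleosome occupancy is the sum of MNase
midpoint counts 1..W bases upstream of the TSS, W ∈ {250, 200, 150, 100}.

## Association statistics

The central contrast is `D = |r_a| − |r_b|` between a mark's correlation
with two paired targets (burst frequency vs burst size; noise vs mean),
Spearman by default because log expression is not normal. Significance
comes from shuffling the intensity vector across genes (1000 rounds,
add-one rule, two-tailed); permuting one side of the pair preserves the
targets' joint structure, which is the correct null for `D`. The permuted
correlations are computed as one matrix product on rank-transformed
vectors, so the test is exact and fast. Partial correlations
rank-transform everything, regress controls out of both focal variables,
and correlate residuals (residual variance at floating-point level is
treated as zero).

Axis grouping z-scores (log2 mean, log2 CV), takes the principal axes
through the centroid, orients the major axis toward increasing expression
and the minor axis toward increasing noise, and assigns: side of the minor
axis = expression high/low; side of the major axis = noise high/low given
expression; groups 1–4 are (high,high), (high,low), (low,high), (low,low).
Points exactly on an axis take the low side; eigenvector signs and tied
eigenvalues are resolved deterministically. The "confident" variant flags
genes whose bootstrap 95% band (1000 seeded resamples of the axis fit) of
signed distances to both axes excludes zero.

Usage preference median-splits each mark over all genes (ties to low) and
tests over-representation of high-intensity genes per group
hypergeometrically against all other groups. The expression-controlled
analysis cuts genes into 10 equal-sized expression bins (ties broken by
stable order), median-splits intensity within each bin, and pools the 2×2
tables with the Mantel–Haenszel common odds ratio; the 95% CI uses the
Robins–Breslow–Greenland variance (via statsmodels' StratifiedTable, which
implements exactly these formulas). Strata with an empty margin are
dropped and logged. Pathway analyses use the relative intensity ratio: a
gene's numerator/denominator mark ratio divided by the median ratio of the
100 control-group genes nearest in |Δ log2 expression|.

## FACS analysis

With two reporters on the same promoter in the same cell, intrinsic noise
is `mean((g − r)²) / (2·ḡ·r̄)` at `μ = sqrt(ḡ·r̄)`. Channels are
mean-normalized by default (making the result unit-free); a raw mode is
provided since the original normalization convention is underdetermined.
Burst frequency at the protein level is the shape parameter of a gamma
fit (MLE with floc = 0, moment-matched initialization and fallback): under
the burst model protein abundance is Gamma(shape = burst frequency,
scale = burst size). Genotype comparisons fit a joint OLS of log2 CV on
log2 μ with a genotype interaction; the interaction p tests slope
flattening.

## Synthetic data

The generator is the package's stand-in for the study's inputs and defines
the conditions every test runs under:

- **Counts.** Latent counts per gene and cell are negative binomial with
  mean `f·b·e_c` and Fano `1 + b` (geometric burst sizes — the telegraph
  limit; the within-burst distribution is a modeling choice). `e_c` is a
  per-embryo multiplicative log-normal factor with unit mean
  (`embryo_effect_sd` on the log scale, default 0). `b = 0` is the Poisson
  limit: single-molecule bursts at rate `f`. Capture is per-molecule
  binomial thinning at efficiency `p` (default 1), mapping Fano
  `F → 1 + p(F−1)`. The matrix is reported in RPKM-like units via one
  global scale so the average column sum equals
  `total_mrna_per_cell × amplification` (defaults 200,000 and 2.75; an
  amplification of 2.75 puts the technical-noise intercept at 0.73). By default
  frequencies are rescaled by a single constant so the expected latent
  transcriptome equals `total_mrna_per_cell` (`match_total_mrna`) — the
  anchoring assumption the calibration relies on; disable it to control
  mean counts directly. Defaults follow the desk-scale design: 5,000
  genes, 200 cells in one group, `f` log-uniform over (0.5, 50), `b`
  log-uniform over (1, 100).
- **Marks.** Per-gene intensity is `ρ·z(log target) + Gaussian noise`
  (noise sd defaults to `sqrt(1−ρ²)` so the planted Pearson correlation is
  exactly ρ), shifted to be positive, and rendered as one peak in the
  promoter window (TSS−2kb..TSS) or across the gene body, so union-
  normalized scoring recovers the planted intensity exactly. Default
  couplings are the two exemplars: an H3K79me2-like gene-body mark on
  burst frequency and an H3K4me3-like promoter mark on expression level,
  both at ρ = 0.6.
- **Two-color FACS.** Each channel is an independent Gamma(α, β) draw
  times a shared log-normal extrinsic factor; intrinsic CV² → 1/α
  regardless of the extrinsic spread. Default 40,000 cells per sample,
  matching the recorded event counts.
- **Midpoint tracks.** Per-gene Poisson counts around a shared positional
  profile.

What the generator does **not** emulate: gene-length and GC biases,
zero-inflation beyond binomial capture, cell-cycle structure, correlated
marks on the same gene, peak-calling noise, or FACS gating artifacts.
Passing tests therefore demonstrate correctness of the estimators under
the burst model's own assumptions, not robustness to every artifact of
real data.

## Problem sizes and numerical choices

Simulation-based checks use 5,000 genes with 200 cells (slope
predictions), 5,000 cells (burst-size recovery), or 1,000-permutation
tests; null-calibration checks use 200 repetitions. The end-to-end mark
contrast simulates a large-cell transcriptome (`total_mrna_per_cell` =
4.5×10⁷, passed to generator and estimator alike) with `f` in (5, 500) and
`b` in (4, 400): with 200,000 molecules spread over 5,000 genes, mean
counts average 40 and no range with burst sizes ≥ 4 keeps every gene
detectable in all cells — the detection boundary (on `f·ln(1+b)`) then
asymmetrically narrows the frequency range and drags a level-coupled
mark's contrast toward burst size. The large-cell regime makes every gene
detectable, so the run isolates the model-level prediction (gene-body mark
D ≫ 0, promoter mark D ≈ 0) from detection-induced selection, which is a
real and separate effect worth knowing about when interpreting filtered
data. Random draws all flow from numpy Generator seeds carried in the
configs; identical seeds give byte-identical outputs.

## Known limitations

- Burst-size estimates inherit the full sampling error of a variance
  estimate; at 20–200 cells individual-gene values are noisy and only
  population-level contrasts are reliable.
- Binomial capture at efficiency `p` biases the calibrated burst size by
  `(1−p)/p` when the calibration re-anchors totals; recovery guarantees in
  the tests hold at `p = 1`.
- The permutation test reports raw p-values; no multiple-testing
  correction is applied across marks.
- KEGG/GO-style enrichment takes user-supplied gene sets only; there is no
  database client.
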