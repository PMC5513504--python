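"""Two-color intrinsic noise and gamma-fit burst frequency from FACS data.

Simulates paired EGFP/dTomato intensities driven by the same promoter (a
shared extrinsic factor times independent gamma draws), decomposes
intrinsic noise, fits the gamma burst model, and contrasts the noise-level
regression between two genotypes with a planted slope difference.
"""

import numpy as np

import burstnoise as bn

# intrinsic noise: identical regulation, shared extrinsic factor
tc = bn.simulate_two_color(n_cells=40_000, alpha=4.0, beta=1.0,
                           extrinsic_sd=0.4, seed=7)
res = bn.intrinsic_noise(tc)
total_cv2 = tc.g.var() / tc.g.mean() ** 2
print(f"total CV^2 (green channel) = {total_cv2:.3f}")
print(f"intrinsic CV^2             = {res.intrinsic_cv2:.3f}  (1/alpha = 0.25)")

fit = bn.fit_gamma(tc.g, normalize_by_red=False)
print(f"gamma fit on green channel: alpha = {fit.alpha:.2f}  "
      f"(includes extrinsic spread, so below the planted 4)")

tc0 = bn.simulate_two_color(n_cells=40_000, alpha=4.0, extrinsic_sd=0.0, seed=8)
fit0 = bn.fit_gamma(tc0, normalize_by_red=False)
print(f"gamma fit without extrinsic noise: alpha = burst frequency = {fit0.alpha:.2f}")

# strain contrast: 7 reporters x 3 replicates per genotype
rng = np.random.default_rng(9)
results = {}
for genotype, slope in [("HO", -0.19), ("DOT1", -0.13)]:
    items = []
    for i in range(7):
        log_mu = 1.0 + i
        for rep in range(3):
            log_cv = -0.4 + slope * log_mu + rng.normal(0, 0.03)
            items.append(bn.facs.IntrinsicNoiseResult(
                reporter=f"R{i}", strain=genotype, replicate=rep,
                mu=2.0**log_mu, intrinsic_cv2=(2.0**log_cv) ** 2, n=40_000))
    results[genotype] = items
contrast = bn.compare_strains(results)
print(f"\nnoise-level slopes: {contrast.slopes['HO']:.3f} (HO) vs "
      f"{contrast.slopes['DOT1']:.3f} (DOT1); interaction p = "
      f"{contrast.interaction_p:.3g}")
print("\nA flatter slope in the writer-deletion background means noise no "
      "longer falls as fast with protein level: the burst-frequency boost "
      "from the gene-body mark is gone.")
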