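"""Expression noise vs expression level under the burst model.

Simulates a cell population where genes differ only in burst frequency,
computes each gene's embryo-corrected CV, and fits the log2 CV vs log2 mean
regression. Under pure frequency modulation noise scales as 1/sqrt(mean),
so the slope should sit at -0.5; pure size modulation flattens it to 0.
"""

import burstnoise as bn

for mode, extra in [
    ("frequency-only", {}),
    ("size-only", dict(burst_size_range=(10.0, 1000.0), fixed_burst_frequency=10.0,
                       match_total_mrna=False)),
]:
    cfg = bn.SimConfig(
        n_genes=5000, groups=(("E1", 200),), regulation_mode=mode, seed=1, **extra
    )
    em, _ = bn.simulate_counts(cfg)
    em = bn.filter_detected(em)
    amp = bn.amplification_factor(em)
    table = bn.noise_cv(em, amplification=amp.A)
    slope, intercept, r = bn.mean_cv_regression(table)
    print(f"{mode:15s}  slope = {slope:+.3f}   Pearson r = {r:+.3f}   "
          f"genes = {len(table)}")

print()
print("The frequency-modulated slope near -0.5 is the Poisson-scaling "
      "signature (noise falls with the square root of expression); the "
      "size-modulated slope near 0 shows burst size changes expression "
      "level without changing noise.")
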