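"""Histone-mark scoring, TSS metaprofiles, and the burst-parameter contrast.

Simulates a gene-body mark coupled to burst frequency and a promoter mark
coupled to expression level, renders them as broadPeak-style peak sets,
scores per-gene intensities (peak-union normalization), and tests whether
each mark is more correlated with burst frequency or burst size.
"""

import burstnoise as bn

total = 45e6  # large-cell transcriptome so every gene is detected
cfg = bn.SimConfig(
    n_genes=3000, groups=(("E1", 200),),
    burst_frequency_range=(5.0, 500.0), burst_size_range=(4.0, 400.0),
    total_mrna_per_cell=total, seed=3,
    mark_coupling={
        "H3K79me2": bn.MarkCoupling("burst_frequency", 0.6, localization="gene_body"),
        "H3K4me3": bn.MarkCoupling("expression_level", 0.6, localization="promoter"),
    },
)
em, truth = bn.simulate_counts(cfg)
ann = bn.make_annotation(em.gene_ids)
peaks = bn.simulate_marks(truth, cfg, ann)

intensity = bn.mark_intensity(peaks, ann, variant="peak_covered_length")
profile, localization = bn.metaprofile(peaks, ann)
print("metaprofile localization calls:", localization.to_dict())

amp = bn.amplification_factor(em, total_mrna_per_cell=total)
em = bn.filter_detected(em)
bursts = bn.estimate_bursts_mrna(em, amplification=amp, cutoff=0.75)
genes = bursts.index.intersection(intensity.index)

for mark in ("H3K79me2", "H3K4me3"):
    res = bn.permutation_test(
        intensity.loc[genes, mark],
        bursts.loc[genes, "burst_frequency"],
        bursts.loc[genes, "burst_size"],
        n_perm=1000, seed=4, mark=mark,
    )
    print(f"{mark:9s}  r_BF = {res.r_a:+.3f}  r_BS = {res.r_b:+.3f}  "
          f"D = |r_BF|-|r_BS| = {res.d:+.3f}  permutation p = {res.p:.4g}")

print()
print("The gene-body mark shows a large positive D (frequency-specific), "
      "while the promoter mark's D sits near zero: level-coupled marks track "
      "frequency and size equally.")
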