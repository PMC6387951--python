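"""Compute the two PLIC asymmetry statistics on a synthetic cohort.

delta_mean is the contralesional-minus-ipsilesional mean; delta_kld is
the half Kullback-Leibler divergence of the two voxel distributions on
a shared 10-bin histogram with James-Stein shrinkage probabilities.
"""

from plicasym import CohortConfig, asymmetry_table, generate_cohort

cfg = CohortConfig(seed=1)
subjects, samples = generate_cohort(cfg)
table = asymmetry_table(samples, region="PLIC", n_bins=10)

odi = table[table.parameter == "ODI"].drop(columns=["region", "parameter"])
print("ODI asymmetry in the PLIC:")
print(odi.to_string(index=False))
print("\nStroke subjects (S*) show negative delta_mean (ODI is elevated "
      "ipsilesionally) and divergences well above the near-zero control "
      "(C*) values, which reflect only sampling noise between symmetric "
      "hemispheres.")
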