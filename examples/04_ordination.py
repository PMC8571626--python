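"""Principal coordinates of Bray–Curtis distances: niches separate.

Embeds the community distance matrix of a simulated two-niche study and
prints the variance explained by the leading axes plus the niche centroids.
"""

import numpy as np

from microstab import (SimulationConfig, bray_curtis, pcoa, simulate_study,
                       to_relative)

study = simulate_study(SimulationConfig(
    n_features_per_niche=200, niches=("endo", "water"), depth_mean=6000, seed=9))
dm = bray_curtis(to_relative(study.counts_table))
res = pcoa(dm, k=2)

print("variance explained: "
      + ", ".join(f"PC{i+1} {p:.1%}" for i, p in
                  enumerate(res.proportion_explained[:2])))
for niche in ("endo", "water"):
    ids = study.metadata.samples_where(niche=niche)
    centroid = res.coordinates.loc[ids].mean()
    print(f"{niche:6s} centroid: PC1 {centroid['PC1']:+.3f}  "
          f"PC2 {centroid['PC2']:+.3f}")
print("\nDistinct niche feature pools put the two niches at opposite ends of"
      "\nPC1; negative eigenvalues (Bray–Curtis is non-Euclidean) are reported"
      "\nby pcoa() but given zero coordinates.")
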