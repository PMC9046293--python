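"""Cytoarchitectonic similarity via Ward clustering of area features.

Simulates profile feature vectors for four areas x two hemispheres (the
classical sampling plan: ~45 profiles per hemisphere), averages them per
unit and clusters the units. Hemispheres of one area should pair first
because within-area hemispheric differences are smaller than between-area
differences.
"""

import numpy as np

from cytoparcel import (
    AreaFeatureSample, aggregate_features, generate_feature_population,
    planned_profile_count, ward_cluster,
)

print(f"sampling plan: {planned_profile_count()} profiles per area "
      "(3 sections x 15 profiles x 2 hemispheres x 10 brains)")

rng = np.random.default_rng(7)
samples = []
for a in range(4):
    base = rng.standard_normal(10) * 4.0  # area-specific laminar signature
    for h in "LR":
        offset = 0.3 * rng.standard_normal(10)  # small hemispheric shift
        x, _ = generate_feature_population(
            [base + offset], np.eye(10), n_per_group=45,
            seed=int(rng.integers(2**31)))
        samples.append(AreaFeatureSample(f"area{a}", h, "pooled", x))

matrix = aggregate_features(samples, level="area_hemisphere")
dend = ward_cluster(matrix)  # z-standardized Euclidean + Ward linkage
print("\nmerge heights (non-decreasing, Ward ultrametric):")
print(np.round(dend.heights, 3))
print("\nNewick dendrogram:")
print(dend.to_newick())
print("-> the four lowest merges should each join the L and R hemisphere "
      "of one area.")
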