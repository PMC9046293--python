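"""Observer-independent border detection on a planted feature stream.

A section is represented by its ordered profile feature vectors; the two
abutting areas differ by 3 pooled standard deviations. The sliding-window
Mahalanobis distance peaks at the border, Hotelling's T-squared with
Bonferroni correction certifies it, and the block-size consistency rule
keeps a single call.
"""

import numpy as np

from cytoparcel import detect_borders, distance_function, two_area_feature_section

features, planted = two_area_feature_section(
    n_traverses=100, border_index=50, contrast_sd=3.0, seed=1)
print(f"synthetic section: 100 profiles, planted border at {planted}")

series = distance_function(features, block_size=20)
k = int(np.argmax(series.distances))
print(f"block size 20: max D^2 = {series.distances[k]:.1f} at position "
      f"{series.positions[k]} (corrected p = {series.p_values[k]:.2e})")

calls = detect_borders(features)  # block sizes 10-24, alpha 0.001
for c in calls:
    print(f"accepted call at position {c.position}, supported by "
          f"{len(c.block_sizes)}/15 block sizes, min corrected p = "
          f"{c.p_min:.2e}")
print("-> the call position should equal the planted border within +/-2 "
      "traverses; a homogeneous section would yield no call.")
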