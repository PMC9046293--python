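"""Probability maps, the maximum probability map and coordinate lookup.

Ten synthetic brains carry the same two-area parcellation displaced by
bounded spatial jitter. Superimposition yields voxelwise probability maps;
the MPM assigns each voxel to its most probable area; centers of gravity
summarize each map; stereotaxic coordinates are assigned by MPM lookup.
"""

import numpy as np

from cytoparcel import (
    center_of_gravity, generate_label_volumes, locate_coordinate,
    maximum_probability_map, probability_map,
)

base = np.zeros((32, 32, 32), np.int32)
base[4:14, 8:24, 8:24] = 1
base[18:28, 8:24, 8:24] = 2
labels = {"Ph1": 1, "Ph2": 2}

volumes = generate_label_volumes(10, base, jitter_vox=2, seed=3,
                                 label_names=labels)
pmaps = [probability_map(volumes, a) for a in labels]
for pm in pmaps:
    print(f"{pm.area}: probability range [{pm.data.min():.1f}, "
          f"{pm.data.max():.1f}] over {pm.n_brains} brains "
          f"(fraction of brains labeling each voxel)")

mpm = maximum_probability_map(pmaps, label_codes=labels)
sizes = {a: int(np.sum(mpm.data == c)) for a, c in labels.items()}
print(f"MPM voxels per area: {sizes} (non-overlapping parcellation)")

for pm in pmaps:
    cog = center_of_gravity(pm)
    print(f"center of gravity of {pm.area}: "
          f"({cog[0]:.1f}, {cog[1]:.1f}, {cog[2]:.1f}) mm")

for xyz in [(9.0, 16.0, 16.0), (23.0, 16.0, 16.0), (16.0, 16.0, 16.0)]:
    print(f"coordinate {xyz} mm -> {locate_coordinate(mpm, xyz)}")
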