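"""Structural Entropy of two phantoms with identical composition.

A half/half slab volume and a thin 16-voxel plane against a 48-voxel bulk:
the first has equal volume fractions (normalized E0 = 1, maximal disorder by
volume alone); the second is volume-imbalanced and also geometrically
asymmetric -- the plane is entirely liminal, so the particle always leaves it,
and the stationary distribution concentrates on the bulk.
"""

import numpy as np

from sementropy import (
    LabeledVolume,
    PhantomSpec,
    full_report,
    generate_phantom,
    liminal_volumes,
    region_volumes,
    transition_matrix,
)

slab = generate_phantom(PhantomSpec(kind="halves", shape=(4, 4, 4)))
labels = np.full((4, 4, 4), 2, dtype=np.int32)
labels[:, :, 0] = 1
thin = LabeledVolume(labels, tag_map={1: "plane", 2: "bulk"})

for name, vol in (("slab", slab), ("thin plane", thin)):
    model = transition_matrix(liminal_volumes(vol, k=1, connectivity="face"),
                              volumes=region_volumes(vol))
    report = full_report(vol, orders=(0, 1, 4))
    print(f"{name}: tags={model.tags}")
    print(f"  Q =\n{np.array_str(model.Q, precision=4)}")
    print(f"  E0_norm = {report.normalized['E0']:.4f}  "
          f"Epi_norm = {report.normalized['Epi']:.4f}  "
          f"(E_max = {report.e_max:.1f} bits)")
# slab: both normalized entropies are exactly 1 (two equal, symmetric tissues).
# thin plane: both drop to ~0.811 -- volume imbalance and geometry agree here
# because the stationary distribution happens to equal the volume fractions.
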