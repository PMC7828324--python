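"""Balance an unbalanced crop collection by rotation/flip augmentation.

Each source crop receives k = ceil(target/n) distinct (angle, flip)
transforms; arbitrary-angle rotations are preceded by bilinear enlargement
(>= sqrt(2)) so the final 200x200 center crop never contains padding.
"""

import numpy as np

from leukomorph import plan_balance
from leukomorph.augmentation import augment_class

counts = {"monocyte": 211, "lymphocyte": 444, "granulocyte": 1540}
plan = plan_balance(counts, target_count=10_000)
for cls, n in counts.items():
    k = plan.transforms_per_source[cls]
    print(f"{cls:12s}: {n:5d} sources x {k:2d} transforms = {plan.total(cls):6d} outputs")

# apply a tiny plan to three real textures to see shapes and provenance
rng = np.random.default_rng(0)
crops = {f"c{i}": rng.integers(0, 256, (200, 200)).astype(np.uint8) for i in range(3)}
small = plan_balance({"demo": 3}, 10, source_ids={"demo": list(crops)})
outputs = augment_class(crops, small, "demo")
print(f"\n{len(outputs)} augmented crops, all "
      f"{outputs[0][1].shape[0]}x{outputs[0][1].shape[1]}; first provenance: "
      f"{outputs[1][2]}")
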