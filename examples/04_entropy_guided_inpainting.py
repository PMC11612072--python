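"""Entropy-guided inpainting pretraining (self-learning).

A local-entropy map decides where and how large removal patches are: many
small holes on informative regions (organ texture, boundaries), few large
ones on flat background.  The backbone then learns to fill the holes, and
finally swaps its regression head for a segmentation head.
"""

import numpy as np

from segpretext.selflearn import (
    adapt_head,
    build_backbone,
    corrupt_image,
    local_entropy,
    mean_fill_rmse,
    plan_inpainting_patches,
    pretrain_inpainting,
)
from segpretext.synthetic_data import PhantomConfig, cohort_slices

cohort = cohort_slices(PhantomConfig(seed=7), 4)
samples = [s for v in cohort.values() for s in v]

emap = local_entropy(samples[0].image)
plan = plan_inpainting_patches(emap, coverage=0.15, rng=0)
cor = corrupt_image(samples[0], plan)
print(f"{len(plan)} patches, sizes {min(p.size_mm for p in plan):.0f}-"
      f"{max(p.size_mm for p in plan):.0f} mm, "
      f"{100 * cor.hole_mask.mean():.0f}% of the slice removed")

model = build_backbone(layers=6, width=8, rng=np.random.default_rng(0))
model, history = pretrain_inpainting(model, samples, steps=120, batch=8, rng=1)
baseline = mean_fill_rmse(samples, rng=2)
print(f"hole RMSE {history[0]:.3f} -> {np.mean(history[-5:]):.3f} "
      f"(mean-fill baseline {baseline:.3f})")

seg = adapt_head(model, rng=3)
print("head swapped to softmax; trunk weights retained:",
      np.array_equal(model.trunk_params()[0].value, seg.trunk_params()[0].value))
# Final RMSE below the mean-fill baseline means the network exploits image
# context rather than filling holes with a constant.
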