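"""Simulate a DCE phantom and recover its kinetic subregions.

Builds a noiseless ellipsoidal phantom whose voxels follow the three
kinetic archetypes, runs the 50%-gate / ±10%-band voxel classifier, and
compares the result with the simulated ground truth.
"""

import numpy as np

from kinhet import PhantomSpec, segment_tumor, simulate_phantom

spec = PhantomSpec(seed=7, class_proportions=(0.3, 0.3, 0.4), noise_sd=0.0)
result = simulate_phantom(spec)
print(f"phantom: {result.tumor_mask.sum()} tumor voxels, "
      f"realized class counts {result.class_counts}")

subregions = segment_tumor(result.series, result.tumor_mask)
agreement = (subregions.labels == result.truth.labels).mean()
print(f"voxel agreement with ground truth: {agreement:.1%}")
# 100% agreement is expected: noiseless archetypes sit well clear of the
# 50% enhancement gate and the ±10% late-change band.

noisy = simulate_phantom(PhantomSpec(seed=7, class_proportions=(0.3, 0.3, 0.4),
                                     noise_sd=8.0))
sub_noisy = segment_tumor(noisy.series, noisy.tumor_mask)
agree_noisy = (sub_noisy.labels == noisy.truth.labels)[noisy.tumor_mask].mean()
print(f"with noise SD 8 (baseline 100): {agree_noisy:.1%} of tumor voxels "
      "keep their true class")
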