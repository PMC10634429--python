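"""Segment a noisy rendering and score it against the known truth.

Runs the seven-step procedure — node extraction, cortex erosion, initial
intensity-band masks, conducting dilation, parenchyma subtraction, overlap
removal, seeded watershed — and reports per-class Dice overlap with the
phantom's ground truth.
"""

import numpy as np

import culm3d
from culm3d.segmentation import params_for_intensity_model

spec = culm3d.suite()["noisy"]
out = culm3d.generate_phantom(spec)
params = params_for_intensity_model(spec.intensity_model, noise_sd=spec.noise_sd)
labels, log = culm3d.run_pipeline(out.grid, params)

print("pipeline steps (voxels out):")
for entry in log:
    print(f"  {entry['step']:<24} {entry['voxels_out']:>8}")

print("\nper-class Dice vs ground truth (1.0 = perfect overlap):")
for cls in ("parenchyma", "fiber", "conducting"):
    a, b = out.truth.mask(cls), labels.mask(cls)
    d = 2 * np.sum(a & b) / (a.sum() + b.sum())
    print(f"  {cls:<12} {d:.3f}")

vf = culm3d.volume_fractions(labels)
print("\nrecovered tissue fractions (percent of the eroded node):")
for _, row in vf.iterrows():
    print(f"  {row['class']:<12} {row['percent']:6.2f} %")
print("\nDice above ~0.85 at this noise level (SNR 3 on the smallest class")
print("gap) means the partition is reliable enough for 3D morphometry.")
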