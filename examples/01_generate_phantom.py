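"""Generate a synthetic branched bamboo node and inspect its ground truth.

The phantom emulates a culm node at desk scale: axial vascular bundles
(conducting core + fiber sheath) on concentric rings in a parenchyma
matrix, a diaphragm slab with transverse bundles, a thin cortex, and an
optional lateral branch whose bundles bifurcate from culm bundles.
"""

import numpy as np

import culm3d

spec = culm3d.suite()["branched"]
out = culm3d.generate_phantom(spec)

print(f"volume shape (z,y,x): {out.truth.shape}, voxel {spec.voxel_size_um} µm")
print(f"bundles in catalog: {len(out.bundle_catalog)} "
      f"({sum(b.kind == 'axial' for b in out.bundle_catalog)} axial, "
      f"{sum(b.kind == 'transverse' for b in out.bundle_catalog)} transverse, "
      f"{sum(b.kind == 'branch' for b in out.bundle_catalog)} branch)")

vf = culm3d.volume_fractions(out.truth)
print("\nground-truth tissue fractions (percent of non-background voxels):")
for _, row in vf.iterrows():
    print(f"  {row['class']:<12} {row['percent']:6.2f} %   {row['volume_mm3']:.4f} mm³")
print("\nThese are the targets the segmentation pipeline must recover; the")
print("conducting tissue is the water-transport phase, the fiber sheaths the")
print("mechanical phase, parenchyma the storage matrix.")

# persist for the other examples (scratch/ is disposable output)
culm3d.write_phantom(out, "scratch/branched_phantom")
print("\nwrote grid.tif / truth.tif / phantom.json to scratch/branched_phantom")
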