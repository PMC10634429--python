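# culm3d

3D vascular-bundle morphometry of bamboo culm nodes from µCT slice stacks.

Bamboo nodes — especially branched nodes, where culm and branch meet — are
the mechanically critical and least understood part of the culm. Inside the
node, vascular bundles (a water-conducting core wrapped in a fiber sheath,
embedded in parenchyma) bend, bifurcate and interconnect through the
diaphragm, forming a 3D network that 2D sections cannot capture. `culm3d`
is a library for quantifying that architecture from reconstructed X-ray
microtomography slice stacks: it segments the node volume into parenchyma,
fibers and conducting tissue, then measures the tissues in 3D and slice by
slice.

It is written for plant anatomists and biomaterials researchers who have a
reconstructed TIFF stack (or want a synthetic stand-in) and need numbers:
tissue volume fractions, local thickness distributions, network
connectivity, bundle counts and sizes.

## What it computes

**Segmentation** (`culm3d.segmentation`) — a seven-step seeded-watershed
procedure: initial fiber/conducting masks from per-tissue intensity bands
(or externally supplied masks), node extraction as the largest bright
26-connected component with per-slice hole filling, per-slice erosion of
2 px to strip the cortex, dilation of the conducting mask to close pores
against the fibers, parenchyma by subtraction, removal of voxels claimed by
two or more masks, and a marker-controlled watershed flood of the remainder.
The flood is a deterministic priority queue ordered by
`(landscape value, insertion index)` over 26-neighbourhoods, with the
gradient magnitude `|∇I|` as the default landscape.

**Morphometry** (`culm3d.morphometry`) — for any binary tissue mask:

- *Local thickness* τ(x) = 2·max{ r : x ∈ B(c, r) ⊆ Ω } — the diameter of
  the largest inscribed sphere covering each voxel (the standard
  trabecular-thickness definition), computed exactly under a documented
  digitization (half-voxel sphere centers, radii measured to the background
  cube-union region).
- *Connected components* under 26-connectivity with volumes in mm³, and a
  connectivity report: components at or above a minimum volume count as
  "connected"; the report quotes connectivity %, largest-component % and
  residual %.
- *Euler characteristic* χ = components − tunnels + cavities by 2×2×2
  configuration counting.
- *Volume fractions* per tissue over the non-background node.

**Profiles** (`culm3d.profiles`) — per-slice tissue areas and proportions,
vascular-bundle footprint counting (8-connected components of the closed
fiber ∪ conducting union), bundle frequency = count / cross-section area
(mm⁻²), axial/transverse classification from footprint elongation and 3D
principal axis, and radial/chord bundle sizes inside a cross-shaped marquee
ROI.

**Phantom generator** (`culm3d.phantom`) — no branched-node µCT volume is
publicly deposited, so the package ships a parametric phantom: a cylindrical
node with axial bundles on concentric rings, a diaphragm slab with
transverse bundles, a thin cortex, an optional diverging branch whose
bundles bifurcate from culm bundles, rendered with tissue-specific
intensities, PSF blur and noise. Ground-truth labels and a bundle catalog
make every downstream stage testable.

## Worked example

`examples/02_segment_and_score.py` renders the noisy reference phantom
(64×112×112 voxels at 7.5 µm, Gaussian noise sd 20 on 8-bit intensities,
0.8-voxel PSF), segments it end to end, and scores the partition against
the known truth:

```
per-class Dice vs ground truth (1.0 = perfect overlap):
  parenchyma   0.942
  fiber        0.858
  conducting   0.935

recovered tissue fractions (percent of the eroded node):
  conducting    11.58 %
  fiber         21.40 %
  parenchyma    67.01 %
```

Dice is the overlap 2|A∩B|/(|A|+|B|) between predicted and true tissue
masks; at this noise level every class stays above 0.85, and on a noise-free
rendering the pipeline recovers the truth almost exactly (Dice ≥ 0.999).

`examples/03_thickness_and_connectivity.py` measures the conducting network
of the branched phantom and also reproduces a printed worked example from
the study the pipeline follows — from fiber component volumes 481.22 +
2.34 + 0.23 mm³ it recomputes:

```
from printed fiber volumes 483.56/483.79 mm³: connectivity 99.95 %, largest 99.47 %
```

i.e. 99.95 % of the fiber volume lies in connected components and the
single largest fiber network holds 99.47 % of it.

The other examples cover phantom generation (`01`) and per-slice profiles,
bundle counting and marquee sizing (`04`). Each prints what the numbers
mean as it goes.

## Command line

A thin CLI wraps the library for stack-in/stack-out use:

```
culm3d generate-phantom --preset branched --out phantom/
culm3d segment --in stack.tif --voxel-um 7.5 --params params.yaml --out labels.tif
culm3d morphometry --labels labels.tif --class conducting --out report.json
culm3d profile --labels labels.tif --slices 0,50,110 --out profile/
culm3d marquee --labels labels.tif --roi roi.json --out sizes.csv
culm3d report --labels labels.tif --out report/
```

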