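# Methods

This note documents the models, conventions and design choices behind
`culm3d`, in the order data flows through the package.

## Coordinate and unit conventions

Volumes are arrays indexed `(z, y, x)`; z is the slice index and increases
from the bottom of the node to the top. All ranges are 0-based and
half-open. Voxels are isotropic; the physical size in µm travels with every
array (the reference acquisition scale is 7.5 µm/voxel). Physical outputs
use µm for thickness, mm² for areas, mm³ for volumes, mm⁻² for bundle
frequency. Anisotropic input is rejected, not resampled.

## The phantom: what it emulates and what it does not

No branched-node µCT volume is publicly deposited, so the package generates
synthetic nodes with known truth. The phantom encodes the qualitative
anatomy of a branched bamboo node:

- a cylindrical culm of parenchyma wrapped in a thin cortex (the cortex is
  a *lateral* shell: the top and bottom faces of the stack are cut
  surfaces, not cortex);
- axial vascular bundles — a conducting core of radius r_c inside a fiber
  sheath of thickness t_s — placed deterministically on concentric rings
  (ring angles staggered between rings; no rejection sampling, so truth is
  reproducible without seed sensitivity);
- one diaphragm slab in which transverse bundles run as radial spokes
  between axial bundles, making the conducting network laterally connected
  there;
- optionally one branch: a cylinder diverging upward/outward whose bundles
  *bifurcate from culm bundles* (each branch bundle's polyline starts on a
  culm bundle centerline), so culm and branch conducting tissue form one
  26-connected component by construction. Branch bundles are half the culm
  calibre — branching bundles are small and dense.
- optional taper and helical-twist parameters for the axial bundles
  (default 0; no quantitative value for either is established, they exist
  to exercise robustness).

Rendering assigns each class a mean intensity (background 20, parenchyma
90, conducting 150, cortex 180, fiber 210 on 8 bits — increasing with
X-ray density), optionally adds per-class texture, convolves with a
Gaussian PSF, adds Gaussian noise, and clips to the dtype. Geometry is
deterministic given the spec; `rng_seed` affects only texture and noise.

Reference study conditions (fixed once, used by tests and the acceptance
script): 64×112×112 voxels at 7.5 µm; node radius 48 voxels; cortex 2
voxels; rings (0.42, 6) and (0.75, 10); r_c = 4 voxels, t_s = 3 voxels;
diaphragm slices [24, 40) with 6 transverse bundles. Three conditions:
*clean* (no blur, no noise), *noisy* (PSF σ = 0.8 voxel, noise sd 20 — the
smallest class gap is 30, so gap/sd ≈ 3, a moderate SNR), *branched*
(branch of radius 16 voxels with 3 bundles, PSF 0.5 voxel, noise sd 10).
These sizes are a deliberate desk-scale stand-in for a full scan
(~1300 slices); they exercise every code path while keeping a full suite
run in tens of seconds.

What the phantom does **not** emulate: beam hardening, ring artifacts,
starch granules, cracks, the medullary cavity, partial-volume anisotropy,
or realistic bundle-shape variation. Passing the recovery tests therefore
shows the *procedure* is correct and noise-tolerant at the stated SNR; it
does not certify accuracy on real scans, where the initial masks (band
thresholds here, a trained segmenter in practice) carry most of the risk.

## Segmentation

The seven steps, and the conventions chosen where the procedure is
underdetermined:

1. **Initial masks.** Per-tissue intensity bands on an optionally smoothed
   image. Band edges sit at midpoints between adjacent class means
   (conducting: (mid(par, cond), mid(cond, fib)]; fiber: above). Two
   hardening measures exist because blur creates partial-volume voxels:
   the conducting mask is opened with a radius-1 Euclidean ball (the
   parenchyma→fiber blend passes straight through the conducting band and
   paints thin shells around every sheath; opening removes shells but not
   solid cores), and seeds can be gated to voxels whose gradient magnitude
   is below a threshold (partial-volume voxels sit on strong edges). The
   fiber mask is never opened: the sheath is itself a thin shell.
   `params_for_intensity_model(model, noise_sd)` enables smoothing, the
   gradient gate and the parenchyma-seed erosion only when noise is
   present, so noise-free data keeps exact bands. External masks (e.g.
   from a learned segmenter) can replace this step.
2. **Node extraction.** Threshold (fixed, or Otsu — note the node
   histogram is multimodal and global Otsu can split parenchyma from
   bundles instead of tissue from air, hence the fixed-midpoint default
   when the intensity model is known), largest 26-connected component,
   per-slice 2D hole filling (lumina belong to the node). An optional
   `exclusion_z_start` keeps only the largest in-plane region on slices at
   or above it — for stacks where the branch has separated from the culm
   and should not be counted.
3. **Cortex erosion.** Per-slice 2D erosion with a Euclidean disk
   (default 2 px). 2D, not 3D: the cortex is a lateral shell, and 3D
   erosion would also shave the node's top and bottom faces.
4. **Conducting dilation.** 3D Euclidean ball, default radius 1 (the
   radius-1 ball is 7 voxels: center + 6 face neighbours). Closes pores
   between conducting tissue and fibers.
5. **Parenchyma** = node ∧ ¬fiber ∧ ¬conducting. On noisy data the
   parenchyma *seed* is additionally eroded by 1 voxel so the
   partial-volume skin around bundles is adjudicated by the watershed, not
   by the subtraction.
6. **Overlap removal.** Every voxel claimed by ≥ 2 masks is dropped from
   all (the conducting dilation margin is the main source).
7. **Seeded watershed.** Priority flood over the eroded node mask,
   26-connectivity, heap ordered by `(landscape value, insertion index)`.
   Landscape: Gaussian gradient magnitude of the grid (σ = 1 voxel) by
   default, or inverse intensity, or a user-supplied array. Seeds are
   enqueued fiber → parenchyma → conducting (raster order within a class):
   on plateaus the earliest-inserted flooder wins, which lets the thin
   sheath keep its skin against the bulk classes and lets fiber reclaim
   the dilation margin. Seed voxels always keep their seed label; voxels
   outside the node are background; an unreachable masked pocket is an
   error rather than a silent hole.

Determinism: every step is deterministic; two runs on the same input are
bit-identical.

## Local thickness

Definition (largest inscribed sphere): τ(x) = 2·max{ r : x ∈ B(c, r) ⊆ Ω }.
Digitization: the mask is read as a union of closed voxel cubes; candidate
centers c live on the half-voxel lattice; the radius at c is its Euclidean
distance to the background region (union of background cubes — rasterized
exactly on the same half-lattice, since cube faces, edges and corners all
lie on it); a sphere covers a voxel when the voxel center lies in the
closed ball. Two consequences: a padded digital slab of t layers measures
exactly t·voxel_size for even *and* odd t (integer-lattice centers cannot
do both), and the transform equals the brute-force definition voxel for
voxel, which the tests assert on digital balls and random blobs.

Implementation: one distance transform gives all radii; a descending sweep
over the distinct radius levels marks, per level r, the voxels within
distance r of any center with radius ≥ r. Cost is one EDT per distinct
level on the doubled lattice, so thickness is meant for masks of modest
size or crops (a bundle crop takes ~1 s; a full 64×112×112 tissue mask is
minutes). Values are reported in µm; 0 outside the mask.

## Components, connectivity, Euler number

Foreground connectivity is 26 and background 6 (the standard complementary
pair), for both labeling and χ. Component ids are deterministic: ordered by
each component's first voxel in scan order. Volumes are exact voxel counts
times the voxel volume. The connected/disconnected split uses a
minimum-component-volume rule (default 125 voxels when driven from the
CLI; the threshold is configurable and the printed worked examples are
reproduced directly from component volumes, independent of it). Reported
percentages are kept at full precision and rounded only at presentation,
2 decimals, half-up. χ is computed by 2×2×2 configuration counting
(scikit-image); the tests pin ball → 1, torus → 0, hollow shell → 2 and
additivity over disjoint unions.

A note on reproducing printed percentages from printed volumes: volumes
rounded to 0.01 mm³ move a quotient like 41.57/46.76 by up to ~0.015
percentage points, so 88.90 can print where 88.91 was computed from
unrounded volumes. The tests allow exactly that slack and no more.

## Per-slice profiles, bundles, marquee

A bundle footprint in a slice is an 8-connected component of the fiber ∪
conducting union after a radius-1 disk closing (merging core and sheath),
kept at ≥ 4 px (both configurable). This is a *definition*, chosen because
bundle counting in the source workflow was visual: it matches the anatomy
(a conducting core inside a fiber sheath) and is testable against the
phantom catalog — slices crossing only axial bundles recover the catalog
count exactly; inside the diaphragm, crossing transverse bundles merge
footprints and the count legitimately drops.

Axial/transverse classification is a heuristic and is always reported with
its features: transverse when in-slice elongation (major/minor axis ratio)
exceeds 3, or when the principal axis of the footprint's 3D component
within ±10 slices deviates more than 45° from z. The window must exceed the
bundle radius, and the angle criterion is skipped when the stack boundary
clips the window (a truncated axial tube would masquerade as transverse).

Marquee measurements: per footprint whose centroid falls in either
rectangle of the cross, the radial length is the voxel-set extent along the
unit vector from the node center through the centroid (+1 voxel for the
voxel's own width), the chord length the extent along the in-plane
perpendicular. The node center defaults to the slice's non-background
centroid. Marquee extents are taken verbatim from configuration and are
not validated against the node size. Summaries are mean ± SD; no
multiple-comparison statistics are attempted.

Per-slice proportions are fractions of the non-background cross-section and
sum to 1; slice areas integrate exactly to the volumetric totals (same
voxel counts).

## Numerical details and degenerate inputs

- Intensity bands are half-open `(lo, hi]`; a class mean exactly on a band
  edge belongs to the lower band.
- Ball/disk structuring elements are Euclidean (`‖d‖ ≤ r` over integer
  offsets).
- Thickness comparisons use a 1e-9 slack on distances; the level values
  themselves are exact square roots of quarter-integers.
- Empty masks: erosion/dilation of empty is empty; an empty mask is an
  error for thickness (undefined) and for volume fractions (no node);
  an empty component table is an error for the connectivity report.
- Degenerate histograms (single intensity value) are errors naming the
  threshold method that failed.
- Rounding for presentation is decimal half-up, 2 decimals, applied only
  in `present()`/reports — never inside computations.

## Known limitations

- The classical initializer assumes ordered, roughly piecewise-constant
  class intensities (fiber > cortex > conducting > parenchyma >
  background); heavy texture or intensity drift calls for external masks.
- The watershed landscape choices (gradient vs inverse intensity) and the
  flood tie rule are documented conventions, not estimates; different
  tools' internals will place plateau boundaries differently at the
  ±1-voxel level.
- Local thickness on large masks is expensive (one EDT per distinct radius
  level); crop or subsample for full-scan work.
- The cortex is removed by a fixed-radius per-slice erosion, which is only
  correct for a roughly vertical node surface; a strongly oblique branch
  exit leaves a partial cortex remnant that ends up in the nearest tissue
  class.
- Transverse-bundle classification fails near the stack's z-boundaries by
  design (it reports the fallback elongation feature only).
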