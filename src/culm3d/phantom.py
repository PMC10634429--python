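"""Synthetic branched-node phantom generator.

Real branched-node µCT volumes are not publicly deposited, so the pipeline
is exercised on synthetic phantoms that emulate the anatomy of a bamboo
branched node at desk scale: a cylindrical culm of parenchyma wrapped in a
thin cortex, axially oriented vascular bundles (a conducting core inside a
fiber sheath) laid out on concentric rings, a diaphragm slab in which
transverse bundles run radially between axial bundles, and an optional
branch whose bundles bifurcate from culm bundles — so culm and branch
conducting tissue form one connected network by construction.

Geometry is deterministic given the spec; the only stochastic stage is the
intensity rendering (texture + noise), driven by ``rng_seed``. Ground-truth
labels, the bundle catalog (centerlines and radii), and the rendered
grayscale volume are all returned, so segmentation and morphometry can be
scored against known truth.

All physical fields are in µm and are converted to voxels at
``voxel_size_um``; features that would collapse below one voxel are
rejected rather than silently rendered.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volio import DEFAULT_CLASS_MAP, LabelVolume, VoxelGrid, write_labels, write_volume

__all__ = [
    "PhantomSpec",
    "BundleEntry",
    "PhantomOutput",
    "generate_phantom",
    "render_intensities",
    "write_phantom",
    "suite",
    "DEFAULT_INTENSITY_MODEL",
]

#: Default 8-bit class means (and per-class texture SD, applied before the
#: PSF). Ordering fiber > cortex > conducting > parenchyma > background
#: mimics X-ray density contrast.
DEFAULT_INTENSITY_MODEL: dict[str, tuple[float, float]] = {
    "background": (20.0, 0.0),
    "parenchyma": (90.0, 0.0),
    "conducting": (150.0, 0.0),
    "cortex": (180.0, 0.0),
    "fiber": (210.0, 0.0),
}


@dataclass
class PhantomSpec:
    """Geometry + imaging parameters of one synthetic branched node.

    Defaults define the package's desk-scale reference node: 64 slices of
    112×112 at 7.5 µm/voxel, a 360 µm-radius culm with 16 axial bundles on
    two rings, a mid-height diaphragm carrying transverse bundles, and no
    branch. ``branch`` is ``(origin_slice, (dz, dy, dx), radius_um,
    bundle_count)``.
    """

    shape: tuple[int, int, int] = (64, 112, 112)
    voxel_size_um: float = 7.5
    node_radius_um: float = 48 * 7.5
    cortex_thickness_um: float = 2 * 7.5
    ring_layout: tuple[tuple[float, int], ...] = ((0.42, 6), (0.75, 10))
    conducting_core_radius_um: float = 4 * 7.5
    fiber_sheath_thickness_um: float = 3 * 7.5
    diaphragm_z_range: tuple[int, int] | None = (24, 40)
    n_transverse_bundles: int = 6
    branch: tuple[int, tuple[float, float, float], float, int] | None = None
    taper_fraction: float = 0.0
    helical_twist_deg: float = 0.0
    intensity_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_MODEL)
    )
    psf_sigma_um: float = 0.0
    noise_sd: float = 0.0
    rng_seed: int = 0

    @property
    def n_axial_bundles(self) -> int:
        return sum(n for _, n in self.ring_layout)

    def validate(self) -> None:
        """Raise ``ValueError`` naming the violated invariant."""
        vs = self.voxel_size_um
        if not (vs > 0):
            raise ValueError("voxel_size_um must be positive")
        nz, ny, nx = self.shape
        if min(self.shape) < 1:
            raise ValueError("shape dimensions must all be >= 1")
        if not (self.cortex_thickness_um < self.node_radius_um):
            raise ValueError(
                "invariant violated: cortex_thickness_um must be < node_radius_um"
            )
        for name, val in (
            ("node_radius_um", self.node_radius_um),
            ("cortex_thickness_um", self.cortex_thickness_um),
        ):
            if val / vs < 1:
                raise ValueError(f"invariant violated: {name} is below one voxel at {vs} µm")
        if self.n_axial_bundles > 0:
            for name, val in (
                ("conducting_core_radius_um", self.conducting_core_radius_um),
                ("fiber_sheath_thickness_um", self.fiber_sheath_thickness_um),
            ):
                if val / vs < 1:
                    raise ValueError(
                        f"invariant violated: {name} is below one voxel at {vs} µm"
                    )
        if self.taper_fraction < 0 or self.taper_fraction >= 1:
            raise ValueError("taper_fraction must lie in [0, 1)")
        centers = _axial_centers(self)
        r_out = (self.conducting_core_radius_um + self.fiber_sheath_thickness_um) / vs
        node_r = self.node_radius_um / vs
        cortex = self.cortex_thickness_um / vs
        cy, cx = (ny - 1) / 2, (nx - 1) / 2
        for y, x in centers:
            if math.hypot(y - cy, x - cx) + r_out > node_r - cortex - 1:
                raise ValueError(
                    "invariant violated: ring_layout places a bundle overlapping the cortex"
                )
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                d = math.hypot(centers[i][0] - centers[j][0], centers[i][1] - centers[j][1])
                if d <= 2 * r_out:
                    raise ValueError(
                        "invariant violated: inter-bundle spacing implied by ring_layout "
                        f"({d:.1f} vox) forces bundles of radius {r_out:.1f} vox to overlap"
                    )
        if self.diaphragm_z_range is not None:
            z0, z1 = self.diaphragm_z_range
            if not (0 <= z0 < z1 <= nz):
                raise ValueError("diaphragm_z_range must be a half-open interval inside the stack")
        if self.n_transverse_bundles > 0:
            if self.diaphragm_z_range is None:
                raise ValueError("transverse bundles require a diaphragm_z_range")
            if self.n_axial_bundles < 2:
                raise ValueError("transverse bundles require >= 2 axial bundles to connect")
        if self.branch is not None:
            z0, direction, radius_um, m = self.branch
            if not (0 <= z0 < nz):
                raise ValueError("branch origin slice outside the stack")
            if radius_um / vs < 1:
                raise ValueError("invariant violated: branch radius is below one voxel")
            if abs(np.linalg.norm(direction) - 1) > 1e-6:
                raise ValueError("branch direction must be a unit vector")
            if direction[0] <= 0:
                raise ValueError("branch direction must point upward (positive z)")
            if m > 0 and self.n_axial_bundles == 0:
                raise ValueError("branch bundles require culm bundles to bifurcate from")

    def to_json(self) -> dict:
        d = asdict(self)
        d["ring_layout"] = [list(r) for r in self.ring_layout]
        return d


@dataclass
class BundleEntry:
    """One catalogued bundle: centerline polyline in (z, y, x) voxel coords."""

    bundle_id: int
    kind: str  # axial | transverse | branch
    polyline: list[tuple[float, float, float]]
    core_radius_um: float
    sheath_thickness_um: float


@dataclass
class PhantomOutput:
    grid: VoxelGrid
    truth: LabelVolume
    bundle_catalog: list[BundleEntry]
    spec: PhantomSpec


def _axial_centers(spec: PhantomSpec) -> list[tuple[float, float]]:
    """Deterministic (y, x) bundle centers at z=0, rings staggered in angle."""
    _, ny, nx = spec.shape
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    node_r = spec.node_radius_um / spec.voxel_size_um
    centers = []
    for ring_i, (frac, n) in enumerate(spec.ring_layout):
        rr = frac * node_r
        for k in range(n):
            theta = 2 * math.pi * k / n + ring_i * math.pi / max(n, 1)
            centers.append((cy + rr * math.sin(theta), cx + rr * math.cos(theta)))
    return centers


def _axial_polyline(spec: PhantomSpec, y0: float, x0: float) -> list[tuple[float, float, float]]:
    nz, ny, nx = spec.shape
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    twist = math.radians(spec.helical_twist_deg)
    pts = []
    for z in range(nz):
        a = twist * z / max(nz - 1, 1)
        dy, dx = y0 - cy, x0 - cx
        y = cy + dy * math.cos(a) - dx * math.sin(a)
        x = cx + dy * math.sin(a) + dx * math.cos(a)
        pts.append((float(z), y, x))
    return pts


def _paint_disk(mask: np.ndarray, z: int, y: float, x: float, r: float) -> None:
    ny, nx = mask.shape[1:]
    y0, y1 = max(0, int(y - r) - 1), min(ny, int(y + r) + 2)
    x0, x1 = max(0, int(x - r) - 1), min(nx, int(x + r) + 2)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.meshgrid(np.arange(y0, y1), np.arange(x0, x1), indexing="ij")
    mask[z, y0:y1, x0:x1] |= (yy - y) ** 2 + (xx - x) ** 2 <= r * r


def _paint_segment_tube(mask: np.ndarray, p: np.ndarray, q: np.ndarray, r: float) -> None:
    """Set voxels within Euclidean distance r of segment pq (z, y, x coords)."""
    lo = np.maximum(np.floor(np.minimum(p, q) - r - 1).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p, q) + r + 1).astype(int) + 1, mask.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1).astype(float)
    d = q - p
    L2 = float(d @ d)
    if L2 == 0:
        dist2 = ((pts - p) ** 2).sum(-1)
    else:
        t = np.clip(((pts - p) @ d) / L2, 0.0, 1.0)
        proj = p + t[..., None] * d
        dist2 = ((pts - proj) ** 2).sum(-1)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= dist2 <= r * r


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Build truth labels, the bundle catalog, and a rendered grayscale volume.

    Deterministic for a fixed spec; only the rendered intensities depend on
    ``rng_seed``. Raises ``ValueError`` on geometrically infeasible specs.
    """
    spec.validate()
    nz, ny, nx = spec.shape
    vs = spec.voxel_size_um
    node_r = spec.node_radius_um / vs
    cortex_px = spec.cortex_thickness_um / vs
    core_r = spec.conducting_core_radius_um / vs
    sheath = spec.fiber_sheath_thickness_um / vs
    cy, cx = (ny - 1) / 2, (nx - 1) / 2

    # Solid node: culm cylinder, plus the branch cylinder when present.
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    culm2d = (yy - cy) ** 2 + (xx - cx) ** 2 <= node_r**2
    solid = np.broadcast_to(culm2d, (nz, ny, nx)).copy()

    branch_axis = None
    if spec.branch is not None:
        z0, direction, radius_um, _ = spec.branch
        d = np.asarray(direction, float)
        p0 = np.array([float(z0), cy, cx])
        t_end = 2.0 * math.hypot(nz, ny, nx)
        branch_axis = (p0, p0 + t_end * d)
        _paint_segment_tube(solid, branch_axis[0], branch_axis[1], radius_um / vs)

    # Cortex: lateral shell of the solid (the EDT does not see past the
    # z-faces of the stack, so top/bottom slices keep their full cross-section).
    edt = ndimage.distance_transform_edt(solid)
    cortex_mask = solid & (edt <= cortex_px)
    interior = solid & ~cortex_mask

    catalog: list[BundleEntry] = []
    sheath_mask = np.zeros(spec.shape, bool)
    core_mask = np.zeros(spec.shape, bool)

    # Axial bundles: per-slice disks following (possibly twisted/tapered)
    # centerlines.
    centers = _axial_centers(spec)
    for y0, x0 in centers:
        poly = _axial_polyline(spec, y0, x0)
        for z, y, x in poly:
            shrink = 1.0 - spec.taper_fraction * z / max(nz - 1, 1)
            _paint_disk(core_mask, int(z), y, x, core_r * shrink)
            _paint_disk(sheath_mask, int(z), y, x, (core_r + sheath) * shrink)
        catalog.append(
            BundleEntry(len(catalog), "axial", poly, spec.conducting_core_radius_um,
                        spec.fiber_sheath_thickness_um)
        )

    # Transverse bundles: radial spokes inside the diaphragm slab connecting
    # pairs of axial bundles, spread over the slab's interior slices.
    if spec.n_transverse_bundles > 0:
        z0, z1 = spec.diaphragm_z_range
        margin = core_r + sheath + 1
        zs = np.linspace(z0 + margin, z1 - 1 - margin, spec.n_transverse_bundles)
        n_ax = len(centers)
        for k in range(spec.n_transverse_bundles):
            a = centers[k % n_ax]
            b = centers[(k + 1 + k // n_ax) % n_ax]
            zk = float(zs[k])
            p = np.array([zk, a[0], a[1]])
            q = np.array([zk, b[0], b[1]])
            _paint_segment_tube(core_mask, p, q, core_r)
            _paint_segment_tube(sheath_mask, p, q, core_r + sheath)
            catalog.append(
                BundleEntry(len(catalog), "transverse",
                            [tuple(p), tuple(q)],
                            spec.conducting_core_radius_um, spec.fiber_sheath_thickness_um)
            )

    # Branch bundles bifurcate from culm bundles: a connector segment from a
    # culm bundle centerline to a small ring around the branch axis, then a
    # run parallel to the axis. Branch bundles are half the culm calibre
    # (branching bundles are small and dense).
    if spec.branch is not None and spec.branch[3] > 0:
        z0, direction, radius_um, m = spec.branch
        d = np.asarray(direction, float)
        b_core, b_sheath = core_r / 2, sheath / 2
        ring_off = min(radius_um / vs - (b_core + b_sheath) - cortex_px - 1,
                       radius_um / vs / 2.5)
        ring_off = max(ring_off, 0.0)
        # two in-plane unit vectors perpendicular to d
        u = np.cross(d, [1.0, 0.0, 0.0])
        if np.linalg.norm(u) < 1e-9:
            u = np.cross(d, [0.0, 1.0, 0.0])
        u /= np.linalg.norm(u)
        w = np.cross(d, u)
        p_axis0 = np.array([float(z0), cy, cx])
        t1 = 2.5 * radius_um / vs
        t_end = 2.0 * math.hypot(nz, ny, nx)
        for k in range(m):
            src = catalog[k % len(centers)]  # a culm axial bundle
            zf, yf, xf = src.polyline[min(z0, nz - 1)]
            p0 = np.array([zf, yf, xf])
            ang = 2 * math.pi * k / m
            off = ring_off * (math.cos(ang) * u + math.sin(ang) * w)
            p1 = p_axis0 + t1 * d + off
            p2 = p_axis0 + t_end * d + off
            for pa, pb in ((p0, p1), (p1, p2)):
                _paint_segment_tube(core_mask, pa, pb, b_core)
                _paint_segment_tube(sheath_mask, pa, pb, b_core + b_sheath)
            catalog.append(
                BundleEntry(len(catalog), "branch",
                            [tuple(p0), tuple(p1), tuple(p2)],
                            spec.conducting_core_radius_um / 2,
                            spec.fiber_sheath_thickness_um / 2)
            )

    # Assemble the partition. Sheaths are painted before cores so conducting
    # cores are never shadowed by another bundle's sheath; bundles are
    # clipped to the interior (never into cortex or background).
    codes = {v: k for k, v in DEFAULT_CLASS_MAP.items()}
    labels = np.zeros(spec.shape, np.uint8)
    labels[interior] = codes["parenchyma"]
    labels[cortex_mask] = codes["cortex"]
    labels[sheath_mask & interior] = codes["fiber"]
    labels[core_mask & interior] = codes["conducting"]
    truth = LabelVolume(labels, dict(DEFAULT_CLASS_MAP), vs)

    grid = render_intensities(truth, spec.intensity_model, spec.psf_sigma_um,
                              spec.noise_sd, spec.rng_seed)
    return PhantomOutput(grid, truth, catalog, spec)


def render_intensities(
    truth: LabelVolume,
    intensity_model: dict[str, tuple[float, float]] | None = None,
    psf_sigma_um: float = 0.0,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    dtype=np.uint8,
) -> VoxelGrid:
    """Render grayscale intensities from a label partition.

    Per-class mean (+ optional per-class texture SD), blurred by a Gaussian
    PSF of ``psf_sigma_um``, plus additive Gaussian noise of ``noise_sd``;
    clipped to the dtype range. Reproducible per ``rng_seed``.
    """
    model = dict(DEFAULT_INTENSITY_MODEL if intensity_model is None else intensity_model)
    present = {truth.class_map[c] for c in np.unique(truth.labels)}
    unknown = present - set(model)
    if unknown:
        raise ValueError(f"intensity model missing classes present in truth: {sorted(unknown)}")
    rng = np.random.default_rng(rng_seed)
    img = np.zeros(truth.shape, np.float64)
    for code, name in truth.class_map.items():
        if name not in model:
            continue
        mean, class_sd = model[name]
        sel = truth.labels == code
        img[sel] = mean
        if class_sd > 0:
            img[sel] += rng.normal(0.0, class_sd, int(sel.sum()))
    sigma_px = psf_sigma_um / truth.voxel_size_um
    if sigma_px > 0:
        img = ndimage.gaussian_filter(img, sigma_px)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    info = np.iinfo(dtype)
    img = np.clip(np.rint(img), info.min, info.max).astype(dtype)
    return VoxelGrid(img, truth.voxel_size_um)


def suite() -> dict[str, PhantomSpec]:
    """The three reference study conditions: clean, noisy, branched.

    ``clean`` is noise- and blur-free; ``noisy`` adds a 0.8-voxel PSF and
    sd-20 noise (minimum class gap / noise = 3); ``branched`` adds a lateral
    branch with bundles bifurcating from culm bundles, lightly noisy.
    """
    branch = (40, _unit((0.55, 0.80, 0.10)), 16 * 7.5, 3)
    return {
        "clean": PhantomSpec(rng_seed=101),
        "noisy": PhantomSpec(psf_sigma_um=0.8 * 7.5, noise_sd=20.0, rng_seed=202),
        "branched": PhantomSpec(branch=branch, psf_sigma_um=0.5 * 7.5, noise_sd=10.0,
                                rng_seed=303),
    }


def _unit(v) -> tuple[float, float, float]:
    a = np.asarray(v, float)
    a = a / np.linalg.norm(a)
    return (float(a[0]), float(a[1]), float(a[2]))


def write_phantom(out: PhantomOutput, directory) -> None:
    """Write grid + truth TIFFs and a JSON sidecar (spec, catalog, legend)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_volume(out.grid, directory / "grid.tif")
    write_labels(out.truth, directory / "truth.tif")
    sidecar = {
        "spec": out.spec.to_json(),
        "class_map": {str(k): v for k, v in out.truth.class_map.items()},
        "bundle_catalog": [
            {
                "bundle_id": b.bundle_id,
                "kind": b.kind,
                "polyline": [list(p) for p in b.polyline],
                "core_radius_um": b.core_radius_um,
                "sheath_thickness_um": b.sheath_thickness_um,
            }
            for b in out.bundle_catalog
        ],
    }
    (directory / "phantom.json").write_text(json.dumps(sidecar, indent=2))
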