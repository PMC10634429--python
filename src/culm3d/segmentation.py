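"""Seven-step seeded-watershed tissue segmentation of a node volume.

The procedure partitions a grayscale node volume into parenchyma, fiber and
conducting tissue:

1. initial fiber/conducting masks from per-tissue intensity bands on a
   smoothed image (or externally supplied masks),
2. node extraction (threshold, largest 26-connected component, per-slice
   hole filling),
3. per-slice 2D erosion of the node mask to strip the cortex,
4. 3D dilation of the conducting mask (closes pores between conducting
   tissue and fibers),
5. parenchyma = node − fibers − dilated conducting,
6. removal of every voxel claimed by two or more masks,
7. marker-controlled watershed flooding from the three disjoint seed sets,
   restricted to the eroded node mask.

The watershed is a deterministic priority flood: voxels enter a heap keyed
by ``(landscape value, insertion index)``; seeds are enqueued class by
class (fiber, then parenchyma, then conducting), raster order within a
class, so equal-landscape contests resolve in favour of the earlier class —
the thin sheath keeps its partial-volume skin against the bulk parenchyma,
and fiber reclaims the safety margin created by the conducting dilation.
Connectivity is 26 in 3D.
"""

from __future__ import annotations

import heapq
import time
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .volio import DEFAULT_CLASS_MAP, LabelVolume, VoxelGrid

__all__ = [
    "InitialTissueMasks",
    "SegmentationParams",
    "bands_from_intensity_model",
    "initial_segment",
    "extract_node_mask",
    "erode_node_mask",
    "dilate_conducting",
    "compute_parenchyma",
    "resolve_overlaps",
    "seeded_watershed",
    "run_pipeline",
]

_CODES = {name: code for code, name in DEFAULT_CLASS_MAP.items()}
#: Flood order: earlier classes win equal-landscape ties. Fiber first — the
#: sheath is a thin shell whose partial-volume skin would otherwise be taken
#: by the bulk classes; conducting last, so fiber reclaims the safety margin
#: created by the conducting dilation.
_SEED_ORDER = ("fiber", "parenchyma", "conducting")


@dataclass
class InitialTissueMasks:
    """Initial (possibly overlapping) fiber and conducting masks."""

    fiber_mask: np.ndarray
    conducting_mask: np.ndarray
    provenance: Literal["classical", "external"] = "classical"

    def __post_init__(self) -> None:
        if self.fiber_mask.shape != self.conducting_mask.shape:
            raise ValueError("fiber and conducting masks must share a shape")


@dataclass
class SegmentationParams:
    """Tunable parameters of the segmentation procedure.

    Intensity bands are half-open ``(lo, hi]`` in grid units; ``None``
    bounds are open. When both bands are ``None`` they are derived from a
    4-class multi-Otsu split of the volume histogram.
    """

    cortex_erosion_px: int = 2
    conducting_dilation_px: int = 1
    node_threshold_method: Literal["otsu", "fixed"] = "otsu"
    node_threshold: float | None = None
    smoothing_sigma_px: float = 1.0
    conducting_band: tuple[float, float | None] | None = None
    fiber_band: tuple[float, float | None] | None = None
    seed_opening_px: int = 1
    seed_max_gradient: float | None = None
    parenchyma_seed_erosion_px: int = 1
    watershed_landscape: Literal["gradient", "inverse_intensity"] = "gradient"
    gradient_sigma_px: float = 1.0
    exclusion_z_start: int | None = None

    def __post_init__(self) -> None:
        if self.cortex_erosion_px < 0 or self.conducting_dilation_px < 0:
            raise ValueError("erosion/dilation radii must be >= 0")
        if self.node_threshold_method == "fixed" and self.node_threshold is None:
            raise ValueError("node_threshold_method='fixed' requires node_threshold")


def bands_from_intensity_model(model: dict) -> tuple[tuple[float, float], tuple[float, None]]:
    """Midpoint intensity bands (conducting, fiber) from per-class means.

    Band edges sit halfway between adjacent tissue means: conducting spans
    (mid(parenchyma, conducting), mid(conducting, fiber)], fiber everything
    above. Partial-volume voxels at tissue interfaces fall outside their
    true class's band; they are deliberately left for the watershed, whose
    seeds are made conservative (conducting opening, parenchyma erosion)
    rather than stretching the bands. Accepts ``{name: mean}`` or
    ``{name: (mean, sd)}``.
    """
    mean = {k: (v[0] if isinstance(v, (tuple, list)) else v) for k, v in model.items()}
    m_par, m_con, m_fib = mean["parenchyma"], mean["conducting"], mean["fiber"]
    if not (m_par < m_con < m_fib):
        raise ValueError("expected parenchyma < conducting < fiber class means")
    hi = (m_con + m_fib) / 2
    return ((m_par + m_con) / 2, hi), (hi, None)


def params_for_intensity_model(
    model: dict, noise_sd: float = 0.0, **overrides
) -> SegmentationParams:
    """Segmentation parameters matched to a known per-class intensity model.

    Uses midpoint bands for the tissue seeds and a fixed node threshold
    halfway between background and parenchyma — global Otsu is unreliable
    on the multimodal node histogram, where the largest variance gap often
    separates bundles from parenchyma instead of tissue from air.

    ``noise_sd`` is the acquisition noise level: on noisy data the bands
    are applied to a smoothed image and seeds are additionally gated to
    low-gradient voxels (partial-volume voxels sit on strong edges, true
    class interiors do not); on noise-free data neither is needed and both
    are disabled so the bands stay exact.
    """
    mean = {k: (v[0] if isinstance(v, (tuple, list)) else v) for k, v in model.items()}
    cond_band, fib_band = bands_from_intensity_model(model)
    kwargs = dict(
        node_threshold_method="fixed",
        node_threshold=(mean["background"] + mean["parenchyma"]) / 2,
        conducting_band=cond_band,
        fiber_band=fib_band,
        smoothing_sigma_px=1.0 if noise_sd > 0 else 0.0,
        seed_max_gradient=(mean["fiber"] - mean["parenchyma"]) / 8 if noise_sd > 0 else None,
        parenchyma_seed_erosion_px=1 if noise_sd > 0 else 0,
    )
    kwargs.update(overrides)
    return SegmentationParams(**kwargs)


def _in_band(img: np.ndarray, band: tuple[float, float | None]) -> np.ndarray:
    lo, hi = band
    out = np.ones(img.shape, bool) if lo is None else img > lo
    if hi is not None:
        out &= img <= hi
    return out


def _ball(radius: int) -> np.ndarray:
    """Euclidean ball structuring element: offsets with ||d|| <= radius."""
    r = int(radius)
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return zz**2 + yy**2 + xx**2 <= r * r


def initial_segment(grid: VoxelGrid, params: SegmentationParams) -> InitialTissueMasks:
    """Classical stand-in for the learned initial segmentation.

    Gaussian smoothing, per-tissue intensity bands, then a radius-1 binary
    opening of the conducting mask only: blur paints a thin partial-volume
    shell through the conducting band wherever parenchyma meets fiber, and
    the opening removes it. The fiber mask is never opened — the sheath is
    itself a thin shell and would not survive. Deterministic.
    """
    img = grid.data.astype(np.float64)
    if params.smoothing_sigma_px > 0:
        img = ndimage.gaussian_filter(img, params.smoothing_sigma_px)
    cond_band, fib_band = params.conducting_band, params.fiber_band
    if cond_band is None and fib_band is None:
        from skimage.filters import threshold_multiotsu

        if np.ptp(grid.data) == 0:
            raise ValueError(
                "degenerate histogram (single intensity value): multi-otsu band "
                "derivation impossible; supply conducting_band/fiber_band"
            )
        t = threshold_multiotsu(img, classes=4)
        cond_band, fib_band = (t[1], t[2]), (t[2], None)
    elif cond_band is None or fib_band is None:
        raise ValueError("supply both conducting_band and fiber_band, or neither")
    fiber = _in_band(img, fib_band)
    conducting = _in_band(img, cond_band)
    if params.seed_max_gradient is not None:
        grad = ndimage.gaussian_gradient_magnitude(
            grid.data.astype(np.float64), max(params.smoothing_sigma_px, 1.0)
        )
        low = grad <= params.seed_max_gradient
        fiber &= low
        conducting &= low
    if params.seed_opening_px > 0:
        conducting = ndimage.binary_opening(
            conducting, structure=_ball(params.seed_opening_px)
        )
    return InitialTissueMasks(fiber, conducting, "classical")


def extract_node_mask(grid: VoxelGrid, params: SegmentationParams) -> np.ndarray:
    """Binary node mask: largest bright 26-component, per-slice hole filling.

    Interior tissue lumina belong to the node, hence the 2D hole filling.
    With ``exclusion_z_start`` set, slices at or above it keep only their
    largest in-plane 8-connected region (drops a separated branch, as done
    for the slices above the culm/branch separation).
    """
    if params.node_threshold_method == "fixed":
        thr = float(params.node_threshold)
    else:
        from skimage.filters import threshold_otsu

        if np.ptp(grid.data) == 0:
            raise ValueError(
                "degenerate histogram (single intensity value): otsu node "
                "threshold impossible; use node_threshold_method='fixed'"
            )
        thr = threshold_otsu(grid.data)
    fg = grid.data > thr
    if not fg.any():
        raise ValueError("empty foreground: no voxels above the node threshold")
    lab, n = ndimage.label(fg, structure=np.ones((3, 3, 3), bool))
    if n > 1:
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        fg = lab == int(np.argmax(counts))
    mask = np.zeros_like(fg)
    for z in range(fg.shape[0]):
        mask[z] = ndimage.binary_fill_holes(fg[z])
    if params.exclusion_z_start is not None:
        s8 = np.ones((3, 3), bool)
        for z in range(max(0, params.exclusion_z_start), mask.shape[0]):
            lab2, n2 = ndimage.label(mask[z], structure=s8)
            if n2 > 1:
                counts = np.bincount(lab2.ravel())
                counts[0] = 0
                mask[z] = lab2 == int(np.argmax(counts))
    return mask


def erode_node_mask(mask: np.ndarray, cortex_erosion_px: int) -> np.ndarray:
    """Per-slice 2D erosion with a Euclidean disk; radius 0 is the identity.

    2D rather than 3D because the cortex is a lateral shell — 3D erosion
    would also shave the node's top and bottom faces.
    """
    r = int(cortex_erosion_px)
    if r < 0:
        raise ValueError("cortex_erosion_px must be >= 0")
    if r == 0 or not mask.any():
        return mask.copy()
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (yy**2 + xx**2 <= r * r)[None]
    return ndimage.binary_erosion(mask, structure=disk, border_value=0)


def dilate_conducting(conducting_mask: np.ndarray, conducting_dilation_px: int) -> np.ndarray:
    """3D dilation by a Euclidean ball (radius 1 ball = 7 voxels)."""
    r = int(conducting_dilation_px)
    if r < 0:
        raise ValueError("conducting_dilation_px must be >= 0")
    if r == 0 or not conducting_mask.any():
        return conducting_mask.copy()
    return ndimage.binary_dilation(conducting_mask, structure=_ball(r))


def compute_parenchyma(
    node_mask: np.ndarray, fiber_mask: np.ndarray, conducting_dilated: np.ndarray
) -> np.ndarray:
    """Parenchyma = node − fibers − (dilated) conducting tissue."""
    if not (node_mask.shape == fiber_mask.shape == conducting_dilated.shape):
        raise ValueError("shape mismatch between node, fiber and conducting masks")
    return node_mask & ~fiber_mask & ~conducting_dilated


def resolve_overlaps(
    fiber: np.ndarray, conducting: np.ndarray, parenchyma: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Remove every voxel claimed by two or more masks from all of them."""
    if not (fiber.shape == conducting.shape == parenchyma.shape):
        raise ValueError("shape mismatch between seed masks")
    multiplicity = (
        fiber.astype(np.uint8) + conducting.astype(np.uint8) + parenchyma.astype(np.uint8)
    )
    single = multiplicity == 1
    return fiber & single, conducting & single, parenchyma & single


_NEIGHBORS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def _compute_landscape(grid: VoxelGrid, kind, sigma: float) -> np.ndarray:
    if isinstance(kind, np.ndarray):
        if kind.shape != grid.shape:
            raise ValueError("precomputed landscape shape mismatch")
        return kind.astype(np.float64)
    img = grid.data.astype(np.float64)
    if kind == "gradient":
        return ndimage.gaussian_gradient_magnitude(img, sigma)
    if kind == "inverse_intensity":
        return img.max() - img
    raise ValueError(f"unknown watershed landscape {kind!r}")


def seeded_watershed(
    grid: VoxelGrid,
    seeds: dict[str, np.ndarray],
    node_mask: np.ndarray,
    watershed_landscape="gradient",
    gradient_sigma_px: float = 1.0,
) -> LabelVolume:
    """Marker-controlled watershed over the node mask.

    ``seeds`` maps class names (parenchyma/fiber/conducting) to disjoint,
    nonempty masks contained in ``node_mask``. ``watershed_landscape`` is
    ``"gradient"`` (Gaussian gradient magnitude of the grid, the default),
    ``"inverse_intensity"``, or a precomputed array. Every node voxel
    reachable from a seed receives exactly one tissue label; seed voxels
    keep their seed label; voxels outside the node mask are background.

    Deterministic: a binary heap ordered by ``(landscape value, insertion
    index)``; seed classes are enqueued in the order parenchyma, fiber,
    conducting (raster order within each class), and flooding uses
    26-connectivity.
    """
    for name in _SEED_ORDER:
        if name not in seeds:
            raise ValueError(f"missing seed class {name!r}")
        if not seeds[name].any():
            raise ValueError(f"empty seed class {name!r}")
        if (seeds[name] & ~node_mask).any():
            raise ValueError(f"seed class {name!r} leaves the node mask")
    for i, a in enumerate(_SEED_ORDER):
        for b in _SEED_ORDER[i + 1 :]:
            if (seeds[a] & seeds[b]).any():
                raise ValueError(
                    f"seeds {a!r} and {b!r} overlap: call resolve_overlaps first"
                )

    landscape = _compute_landscape(grid, watershed_landscape, gradient_sigma_px)

    # Pad by one so the 26-neighbourhood never leaves the array.
    land = np.pad(landscape, 1, constant_values=0.0).ravel()
    inside = np.pad(node_mask, 1, constant_values=False).ravel()
    lab_arr = np.zeros_like(node_mask, np.uint8)
    for name in _SEED_ORDER:
        lab_arr[seeds[name]] = _CODES[name]
    lab = np.pad(lab_arr, 1, constant_values=0).ravel()

    pz, py, px = (s + 2 for s in node_mask.shape)
    offs = [dz * py * px + dy * px + dx for dz, dy, dx in _NEIGHBORS_26]

    heap: list[tuple[float, int, int, int]] = []
    push, pop = heapq.heappush, heapq.heappop
    counter = 0
    for name in _SEED_ORDER:
        code = _CODES[name]
        padded_seed = np.pad(seeds[name], 1, constant_values=False)
        for i in np.flatnonzero(padded_seed.ravel()):
            i = int(i)
            for off in offs:
                j = i + off
                if inside[j] and lab[j] == 0:
                    push(heap, (land[j], counter, j, code))
                    counter += 1
    while heap:
        _, _, j, code = pop(heap)
        if lab[j] != 0:
            continue
        lab[j] = code
        for off in offs:
            k = j + off
            if inside[k] and lab[k] == 0:
                push(heap, (land[k], counter, k, code))
                counter += 1

    out = lab.reshape(pz, py, px)[1:-1, 1:-1, 1:-1].copy()
    if bool((inside.reshape(pz, py, px)[1:-1, 1:-1, 1:-1] & (out == 0)).any()):
        raise ValueError("node mask contains regions unreachable from any seed")
    class_map = {0: "background", **{c: n for n, c in _CODES.items() if n in _SEED_ORDER}}
    return LabelVolume(out, class_map, grid.voxel_size_um)


def run_pipeline(
    grid: VoxelGrid,
    params: SegmentationParams | None = None,
    initial_masks: InitialTissueMasks | None = None,
) -> tuple[LabelVolume, list[dict]]:
    """Execute the seven-step procedure end to end.

    Returns the tissue partition plus a provenance record: one entry per
    step with voxel counts entering/leaving and wall time. Deterministic
    given the inputs.
    """
    params = params or SegmentationParams()
    log: list[dict] = []

    def step(name, func, *args):
        t0 = time.perf_counter()
        try:
            result = func(*args)
        except Exception as exc:
            raise type(exc)(f"[{name}] {exc}") from exc
        log.append(
            {
                "step": name,
                "voxels_out": int(np.sum(result.labels != 0))
                if isinstance(result, LabelVolume)
                else (int(result.sum()) if isinstance(result, np.ndarray) else None),
                "wall_s": time.perf_counter() - t0,
            }
        )
        return result

    if initial_masks is None:
        t0 = time.perf_counter()
        initial_masks = initial_segment(grid, params)
        log.append(
            {
                "step": "initial_segment",
                "voxels_out": int(initial_masks.fiber_mask.sum())
                + int(initial_masks.conducting_mask.sum()),
                "wall_s": time.perf_counter() - t0,
            }
        )
    node = step("extract_node_mask", extract_node_mask, grid, params)
    eroded = step("erode_node_mask", erode_node_mask, node, params.cortex_erosion_px)
    cond_dil = step(
        "dilate_conducting", dilate_conducting, initial_masks.conducting_mask,
        params.conducting_dilation_px,
    )
    fiber = initial_masks.fiber_mask & eroded
    cond_dil = cond_dil & eroded
    parenchyma = step("compute_parenchyma", compute_parenchyma, eroded, fiber, cond_dil)
    if params.parenchyma_seed_erosion_px > 0:
        # Conservative parenchyma seed: drop the partial-volume shell along
        # bundle boundaries so the watershed, not the subtraction, places them.
        t0 = time.perf_counter()
        parenchyma = ndimage.binary_erosion(
            parenchyma, structure=_ball(params.parenchyma_seed_erosion_px)
        )
        log.append(
            {
                "step": "erode_parenchyma_seed",
                "voxels_out": int(parenchyma.sum()),
                "wall_s": time.perf_counter() - t0,
            }
        )
    t0 = time.perf_counter()
    fiber_s, cond_s, par_s = resolve_overlaps(fiber, cond_dil, parenchyma)
    log.append(
        {
            "step": "resolve_overlaps",
            "voxels_out": int(fiber_s.sum() + cond_s.sum() + par_s.sum()),
            "wall_s": time.perf_counter() - t0,
        }
    )
    labels = step(
        "seeded_watershed",
        seeded_watershed,
        grid,
        {"parenchyma": par_s, "fiber": fiber_s, "conducting": cond_s},
        eroded,
        params.watershed_landscape,
        params.gradient_sigma_px,
    )
    return labels, log
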