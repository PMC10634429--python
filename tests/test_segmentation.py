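import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import culm3d
from culm3d.segmentation import (
    SegmentationParams,
    compute_parenchyma,
    dilate_conducting,
    erode_node_mask,
    extract_node_mask,
    initial_segment,
    params_for_intensity_model,
    resolve_overlaps,
    run_pipeline,
    seeded_watershed,
)
from culm3d.volio import VoxelGrid
from helpers import exhaustive_flood, random_flood_instance
from test_phantom import small_spec

CODES = {"parenchyma": 1, "fiber": 2, "conducting": 3}


# --------------------------------------------------------------- initial masks
def test_initial_masks_equal_truth_on_piecewise_constant_image():
    """With bands bracketing the class means and no smoothing, the bands
    recover the truth sets exactly on a noise- and blur-free rendering."""
    out = culm3d.generate_phantom(small_spec())
    params = SegmentationParams(
        conducting_band=(120, 180),
        fiber_band=(180, None),
        smoothing_sigma_px=0.0,
        seed_opening_px=0,
    )
    init = initial_segment(out.grid, params)
    # bands also catch the cortex (rendered above the fiber threshold); the
    # truth comparison is made inside the cortex-free interior
    interior = ~out.truth.mask("cortex")
    assert np.array_equal(init.fiber_mask & interior, out.truth.mask("fiber"))
    assert np.array_equal(init.conducting_mask & interior, out.truth.mask("conducting"))


def test_initial_masks_empty_on_all_background():
    grid = VoxelGrid(np.full((6, 6, 6), 20, np.uint8), 7.5)
    params = SegmentationParams(conducting_band=(120, 180), fiber_band=(180, None))
    init = initial_segment(grid, params)
    assert not init.fiber_mask.any() and not init.conducting_mask.any()


def test_degenerate_histogram_errors_name_threshold_method():
    grid = VoxelGrid(np.full((6, 6, 6), 50, np.uint8), 7.5)
    with pytest.raises(ValueError, match="multi-otsu"):
        initial_segment(grid, SegmentationParams())
    with pytest.raises(ValueError, match="otsu"):
        extract_node_mask(grid, SegmentationParams())


# ------------------------------------------------------------------- node mask
def test_node_mask_contains_all_tissue_and_keeps_larger_of_two_cylinders():
    out = culm3d.generate_phantom(small_spec())
    params = params_for_intensity_model(out.spec.intensity_model)
    node = extract_node_mask(out.grid, params)
    assert bool(((out.truth.labels != 0) <= node).all())

    # two disjoint cylinders: only the larger is retained
    img = np.zeros((10, 40, 40), np.uint8)
    yy, xx = np.mgrid[:40, :40]
    img[:, (yy - 12) ** 2 + (xx - 12) ** 2 <= 81] = 200
    img[:, (yy - 30) ** 2 + (xx - 30) ** 2 <= 16] = 200
    grid = VoxelGrid(img, 1.0)
    node = extract_node_mask(grid, SegmentationParams(
        node_threshold_method="fixed", node_threshold=100))
    assert node[:, 12, 12].all() and not node[:, 30, 30].any()


def test_empty_foreground_errors():
    grid = VoxelGrid(np.zeros((4, 4, 4), np.uint8), 1.0)
    with pytest.raises(ValueError, match="empty foreground"):
        extract_node_mask(grid, SegmentationParams(
            node_threshold_method="fixed", node_threshold=100))


def test_exclusion_z_keeps_only_largest_in_plane_region():
    img = np.zeros((6, 20, 20), np.uint8)
    img[:, 2:10, 2:10] = 200          # culm, all slices
    img[:, 14:18, 14:18] = 200        # branch: in-plane separate from culm
    img[:3, 9:15, 9:15] = 200         # low-z bridge keeps one 3D component
    grid = VoxelGrid(img, 1.0)
    params = SegmentationParams(node_threshold_method="fixed", node_threshold=100,
                                exclusion_z_start=3)
    node = extract_node_mask(grid, params)
    assert node[1, 15, 15]
    assert not node[4, 15, 15] and node[4, 5, 5]


# ---------------------------------------------------------- erosion / dilation
def brute_erode_2d(mask2d, r):
    offs = [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1)
            if dy * dy + dx * dx <= r * r]
    ny, nx = mask2d.shape
    out = np.zeros_like(mask2d)
    for y in range(ny):
        for x in range(nx):
            out[y, x] = all(
                0 <= y + dy < ny and 0 <= x + dx < nx and mask2d[y + dy, x + dx]
                for dy, dx in offs
            )
    return out


def test_erosion_matches_brute_force_disk_oracle():
    yy, xx = np.mgrid[:25, :25]
    disk = ((yy - 12) ** 2 + (xx - 12) ** 2 <= 100)[None]
    got = erode_node_mask(disk, 2)
    assert np.array_equal(got[0], brute_erode_2d(disk[0], 2))
    assert (got <= disk).all()


def test_erosion_zero_is_identity_and_empty_is_empty():
    rng = np.random.default_rng(0)
    m = rng.random((3, 10, 10)) < 0.5
    assert np.array_equal(erode_node_mask(m, 0), m)
    assert not erode_node_mask(np.zeros((2, 4, 4), bool), 2).any()


def test_eroded_node_mask_is_disjoint_from_cortex(phantoms, segmentations):
    out = phantoms["clean"]
    _, _, params = segmentations["clean"]
    node = extract_node_mask(out.grid, params)
    eroded = erode_node_mask(node, params.cortex_erosion_px)
    assert not (eroded & out.truth.mask("cortex")).any()


def test_dilation_ball_radius_one_is_seven_voxels():
    """Euclidean ball of radius 1 = center + 6 face neighbours."""
    m = np.zeros((5, 5, 5), bool)
    m[2, 2, 2] = True
    got = dilate_conducting(m, 1)
    assert int(got.sum()) == 7
    assert np.array_equal(dilate_conducting(m, 0), m)
    assert (m <= got).all()


# ------------------------------------------------------ set algebra operations
def test_parenchyma_subtraction_matches_set_oracle():
    rng = np.random.default_rng(3)
    node = rng.random((4, 6, 6)) < 0.8
    fib = (rng.random((4, 6, 6)) < 0.3) & node
    con = (rng.random((4, 6, 6)) < 0.3) & node
    got = compute_parenchyma(node, fib, con)
    for idx in np.ndindex(node.shape):
        assert got[idx] == (node[idx] and not fib[idx] and not con[idx])
    assert np.array_equal(compute_parenchyma(node, np.zeros_like(node),
                                             np.zeros_like(node)), node)
    assert not compute_parenchyma(node, node, np.zeros_like(node)).any()
    with pytest.raises(ValueError, match="shape"):
        compute_parenchyma(node, fib[:2], con)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    f=arrays(bool, (3, 4, 4), elements=st.booleans()),
    c=arrays(bool, (3, 4, 4), elements=st.booleans()),
    p=arrays(bool, (3, 4, 4), elements=st.booleans()),
)
def test_resolve_overlaps_properties(f, c, p):
    """Outputs are pairwise disjoint, solely-claimed voxels are unchanged,
    and multiply-claimed voxels vanish from every mask."""
    rf, rc, rp = resolve_overlaps(f, c, p)
    assert not (rf & rc).any() and not (rf & rp).any() and not (rc & rp).any()
    mult = f.astype(int) + c.astype(int) + p.astype(int)
    for got, orig in ((rf, f), (rc, c), (rp, p)):
        assert np.array_equal(got, orig & (mult == 1))


def test_resolve_overlaps_matches_multiplicity_oracle():
    rng = np.random.default_rng(4)
    masks = [rng.random((4, 5, 5)) < 0.5 for _ in range(3)]
    f, c, p = resolve_overlaps(*masks)
    mult = sum(m.astype(int) for m in masks)
    for got, orig in zip((f, c, p), masks):
        assert np.array_equal(got, orig & (mult == 1))
    assert not (f & c).any() and not (f & p).any() and not (c & p).any()
    # disjoint inputs unchanged
    a = np.zeros((2, 2, 2), bool); a[0, 0, 0] = True
    b = np.zeros((2, 2, 2), bool); b[1, 1, 1] = True
    d = np.zeros((2, 2, 2), bool); d[0, 1, 0] = True
    assert all(np.array_equal(x, y) for x, y in zip(resolve_overlaps(a, b, d), (a, b, d)))
    # a voxel claimed by all three vanishes from all outputs
    t = np.ones((1, 1, 1), bool)
    assert not any(m.any() for m in resolve_overlaps(t, t.copy(), t.copy()))


# -------------------------------------------------------------------- watershed
def _grid(shape):
    return VoxelGrid(np.zeros(shape, np.uint8), 1.0)


def test_watershed_identity_when_seeds_cover_mask():
    rng = np.random.default_rng(5)
    mask = np.ones((3, 4, 4), bool)
    codes = rng.integers(1, 4, mask.shape)
    seeds = {n: (codes == c) for n, c in CODES.items()}
    land = rng.random(mask.shape)
    out = seeded_watershed(_grid(mask.shape), seeds, mask, land)
    assert np.array_equal(out.labels, codes)


def test_watershed_hand_traced_ridge_assignment():
    """On a 1D double-ridge landscape each basin goes to its seed and the
    ridge voxels go to the earliest-inserted flooder (fiber, here)."""
    land = np.array([[[0, 1, 9, 1, 0, 1, 9, 1, 0]]], float)
    mask = np.ones((1, 1, 9), bool)
    seeds = {n: np.zeros_like(mask) for n in CODES}
    seeds["fiber"][0, 0, 0] = True
    seeds["conducting"][0, 0, 4] = True
    seeds["parenchyma"][0, 0, 8] = True
    out = seeded_watershed(_grid(mask.shape), seeds, mask, land)
    assert out.labels[0, 0].tolist() == [2, 2, 2, 3, 3, 3, 1, 1, 1]


def test_watershed_errors_name_the_failing_seed_class():
    mask = np.ones((2, 2, 2), bool)
    seeds = {n: np.zeros_like(mask) for n in CODES}
    seeds["fiber"][0, 0, 0] = True
    seeds["parenchyma"][1, 1, 1] = True
    with pytest.raises(ValueError, match="conducting"):
        seeded_watershed(_grid(mask.shape), seeds, mask, np.zeros(mask.shape))
    seeds["conducting"][0, 0, 0] = True  # overlaps fiber
    with pytest.raises(ValueError, match="resolve_overlaps"):
        seeded_watershed(_grid(mask.shape), seeds, mask, np.zeros(mask.shape))


def test_watershed_preserves_seeds_and_matches_oracle_on_small_instances():
    rng = np.random.default_rng(6)
    for _ in range(10):
        land, mask, seeds = random_flood_instance(rng)
        oracle = exhaustive_flood(land, seeds, mask)
        try:
            out = seeded_watershed(_grid(mask.shape), seeds, mask, land).labels
        except ValueError:
            assert (oracle[mask] == 0).any()  # unreachable pocket
            continue
        assert np.array_equal(out, oracle)
        for name, code in CODES.items():
            assert np.all(out[seeds[name]] == code)


# --------------------------------------------------------------------- pipeline
def test_pipeline_is_deterministic_and_logs_steps():
    out = culm3d.generate_phantom(small_spec(noise_sd=10.0, psf_sigma_um=5.0))
    params = params_for_intensity_model(out.spec.intensity_model, noise_sd=10.0)
    l1, log1 = run_pipeline(out.grid, params)
    l2, _ = run_pipeline(out.grid, params)
    assert np.array_equal(l1.labels, l2.labels)
    steps = [e["step"] for e in log1]
    assert steps[0] == "initial_segment" and steps[-1] == "seeded_watershed"


def test_pipeline_all_parenchyma_phantom_errors_on_empty_seed():
    out = culm3d.generate_phantom(small_spec(ring_layout=()))
    params = params_for_intensity_model(out.spec.intensity_model)
    with pytest.raises(ValueError, match="empty seed class"):
        run_pipeline(out.grid, params)


def test_pipeline_respects_external_initial_masks(phantoms):
    """Truth-derived external masks drive the pipeline to the truth."""
    from culm3d.segmentation import InitialTissueMasks

    out = phantoms["clean"]
    ext = InitialTissueMasks(out.truth.mask("fiber"),
                             out.truth.mask("conducting"), "external")
    params = params_for_intensity_model(out.spec.intensity_model)
    labels, _ = run_pipeline(out.grid, params, initial_masks=ext)
    from conftest import dice

    for cls in ("parenchyma", "fiber", "conducting"):
        assert dice(labels.mask(cls), out.truth.mask(cls)) > 0.97
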