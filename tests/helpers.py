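"""Independent brute-force oracles used by the test suite.

These deliberately avoid the algorithms used in the package: the thickness
oracle enumerates sphere centers pairwise with KD-trees instead of
level-set distance transforms; the flood oracle is a heap-free linear scan
instead of a priority queue.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from culm3d.segmentation import _CODES, _SEED_ORDER


def brute_local_thickness(mask: np.ndarray) -> np.ndarray:
    """Largest-inscribed-sphere thickness by exhaustive center enumeration.

    Same digitization contract as the package (half-voxel centers, radius =
    distance to the background cube-union region, closed-ball coverage) but
    computed by brute force: enumerate every candidate center, get its
    radius from a KD-tree over background-region points, then for every
    mask voxel take the best covering center.
    """
    mask = np.asarray(mask, bool)
    nz, ny, nx = mask.shape
    bg_pts = set()
    for z, y, x in np.argwhere(~mask):
        for dz in (-0.5, 0.0, 0.5):
            for dy in (-0.5, 0.0, 0.5):
                for dx in (-0.5, 0.0, 0.5):
                    bg_pts.add((z + dz, y + dy, x + dx))
    axes = [np.arange(0, s - 0.5, 0.5) for s in (nz, ny, nx)]
    centers = np.stack(
        np.meshgrid(*axes, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    if bg_pts:
        tree = cKDTree(np.array(sorted(bg_pts)))
        radii, _ = tree.query(centers)
    else:
        radii = np.full(len(centers), 1e9)
    keep = radii > 1e-9
    centers, radii = centers[keep], radii[keep]
    th = np.zeros(mask.shape)
    for v in np.argwhere(mask):
        d = np.sqrt(((centers - v) ** 2).sum(1))
        covering = d <= radii + 1e-9
        if covering.any():
            th[tuple(v)] = 2.0 * radii[covering].max()
    return th


def exhaustive_flood(
    landscape: np.ndarray, seeds: dict[str, np.ndarray], mask: np.ndarray
) -> np.ndarray:
    """Lowest-cost flooding by exhaustive linear scan (no heap).

    Frontier candidates are (landscape value, insertion index, voxel,
    label); each step assigns the minimum candidate and extends the
    frontier, with seed classes inserted in the package's documented order.
    """
    nz, ny, nx = landscape.shape
    lab = np.zeros((nz, ny, nx), np.uint8)
    for name in _SEED_ORDER:
        lab[seeds[name]] = _CODES[name]

    def neighbors(z, y, x):
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dz == dy == dx == 0:
                        continue
                    w = (z + dz, y + dy, x + dx)
                    if 0 <= w[0] < nz and 0 <= w[1] < ny and 0 <= w[2] < nx:
                        yield w

    cand: list[tuple[float, int, tuple, int]] = []
    counter = 0
    for name in _SEED_ORDER:
        code = _CODES[name]
        for z, y, x in np.argwhere(seeds[name]):
            for w in neighbors(z, y, x):
                if mask[w] and lab[w] == 0:
                    cand.append((float(landscape[w]), counter, w, code))
                    counter += 1
    while cand:
        best = min(range(len(cand)), key=lambda i: (cand[i][0], cand[i][1]))
        _, _, w, code = cand.pop(best)
        if lab[w] != 0:
            continue
        lab[w] = code
        for u in neighbors(*w):
            if mask[u] and lab[u] == 0:
                cand.append((float(landscape[u]), counter, u, code))
                counter += 1
    return lab


def random_flood_instance(rng, shape=(5, 5, 5), seeds_per_class=2):
    """A random landscape/mask/seed triple with three disjoint seed classes."""
    while True:
        land = rng.random(shape)
        mask = rng.random(shape) < 0.9
        idx = np.argwhere(mask)
        if len(idx) < 3 * seeds_per_class:
            continue
        rng.shuffle(idx)
        seeds = {}
        for k, name in enumerate(_SEED_ORDER):
            s = np.zeros(shape, bool)
            for j in range(seeds_per_class):
                s[tuple(idx[seeds_per_class * k + j])] = True
            seeds[name] = s
        return land, mask, seeds
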