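"""Volume and label I/O with physical metadata.

Volumes are TIFF slice stacks — either a single multi-page TIFF or a
directory of equally shaped single-page TIFFs ordered by the numeric value
embedded in their filenames (natural sort, so ``s2`` precedes ``s10``).
Arrays are indexed ``(z, y, x)`` with z the slice index increasing from the
bottom of the node to the top. Voxels are isotropic; the physical voxel
size in µm travels with the array, either passed explicitly or read from a
JSON sidecar written next to the TIFF.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "VoxelGrid",
    "LabelVolume",
    "MarqueeROI",
    "DEFAULT_CLASS_MAP",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
]

#: Canonical tissue class codes used throughout the package.
DEFAULT_CLASS_MAP: dict[int, str] = {
    0: "background",
    1: "parenchyma",
    2: "fiber",
    3: "conducting",
    4: "cortex",
}

_VALID_CLASS_NAMES = frozenset(DEFAULT_CLASS_MAP.values())


@dataclass
class VoxelGrid:
    """A 3D grayscale intensity volume with isotropic voxel size in µm."""

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3D with all dims >= 1, got shape {self.data.shape}")
        if not (self.voxel_size_um > 0):
            raise ValueError(f"voxel_size_um must be positive, got {self.voxel_size_um}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size_um * 1e-3) ** 3


@dataclass
class LabelVolume:
    """A per-voxel tissue partition.

    Every voxel carries exactly one code present in ``class_map``; codes map
    to the five tissue names (background, parenchyma, fiber, conducting,
    cortex).
    """

    labels: np.ndarray
    class_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_MAP))
    voxel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {self.labels.shape}")
        if not (self.voxel_size_um > 0):
            raise ValueError(f"voxel_size_um must be positive, got {self.voxel_size_um}")
        bad = set(self.class_map.values()) - _VALID_CLASS_NAMES
        if bad:
            raise ValueError(f"unknown class names in class_map: {sorted(bad)}")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.class_map)
        if missing:
            raise ValueError(
                f"labels contain codes absent from class_map: {sorted(missing)} "
                "(every voxel must carry a mapped code)"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def code_of(self, name: str) -> int:
        for code, cname in self.class_map.items():
            if cname == name:
                return code
        raise KeyError(f"class {name!r} not in class_map")

    def mask(self, name: str) -> np.ndarray:
        """Binary mask of one tissue class."""
        return self.labels == self.code_of(name)


@dataclass
class MarqueeROI:
    """A cross-shaped pair of rectangles on one slice.

    The two rectangles cross at ``center`` (y, x voxel coordinates). Each
    has a radial and a chord extent in mm; "radial" is the direction from
    the node center through the marquee center (falling back to +y when the
    two coincide), "chord" its in-plane perpendicular.
    """

    slice_index: int
    center: tuple[float, float]
    rect_a: tuple[float, float]  # (radial_extent_mm, chord_extent_mm)
    rect_b: tuple[float, float]

    def __post_init__(self) -> None:
        for name, (r, c) in (("rect_a", self.rect_a), ("rect_b", self.rect_b)):
            if not (r > 0 and c > 0):
                raise ValueError(f"{name} extents must be positive, got {(r, c)}")


def _natural_key(name: str) -> tuple:
    """Sort key ordering embedded integers numerically (s2 < s10)."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _sidecar_path(path: Path) -> Path:
    if path.is_dir():
        return path / "volume.json"
    return path.with_suffix(path.suffix + ".json")


def _read_stack(path: Path) -> np.ndarray:
    if path.is_dir():
        pages = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")),
            key=lambda p: _natural_key(p.name),
        )
        if not pages:
            raise FileNotFoundError(f"no TIFF slices found in directory {path}")
        slices = []
        for p in pages:
            try:
                slices.append(tifffile.imread(p))
            except Exception as exc:  # pragma: no cover - corrupt file path
                raise OSError(f"unreadable TIFF page {p}: {exc}") from exc
        shapes = {s.shape for s in slices}
        if len(shapes) > 1:
            raise ValueError(f"ragged slice shapes in {path}: {sorted(shapes)}")
        return np.stack(slices, axis=0)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2D/3D TIFF stack at {path}, got ndim={arr.ndim}")
    return arr


def read_volume(path, voxel_size_um: float | None = None) -> VoxelGrid:
    """Read a grayscale stack; slice order is ascending page/filename order.

    ``voxel_size_um`` may be omitted when a JSON sidecar (written by
    :func:`write_volume`) records it.
    """
    path = Path(path)
    arr = _read_stack(path)
    if voxel_size_um is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            voxel_size_um = json.loads(sidecar.read_text()).get("voxel_size_um")
    if voxel_size_um is None:
        raise ValueError(
            f"voxel size missing: pass voxel_size_um or provide sidecar {_sidecar_path(path)}"
        )
    return VoxelGrid(arr, float(voxel_size_um))


def write_volume(grid: VoxelGrid, path) -> None:
    """Write a multi-page TIFF plus a JSON sidecar with the voxel size.

    Lossless: :func:`read_volume` round-trips the array bit-exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, grid.data, photometric="minisblack")
    _sidecar_path(path).write_text(
        json.dumps({"voxel_size_um": grid.voxel_size_um, "shape": list(grid.shape)}, indent=2)
    )


def write_labels(labels: LabelVolume, path) -> None:
    """Write class codes as an unsigned-int TIFF with the legend in a sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    codes = labels.labels
    if codes.dtype.kind != "u":
        if codes.min() < 0:
            raise ValueError("label codes must be non-negative")
        codes = codes.astype(np.uint16 if codes.max() > 255 else np.uint8)
    tifffile.imwrite(path, codes, photometric="minisblack")
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "voxel_size_um": labels.voxel_size_um,
                "shape": list(labels.shape),
                "class_map": {str(k): v for k, v in labels.class_map.items()},
            },
            indent=2,
        )
    )


def read_labels(path, voxel_size_um: float | None = None) -> LabelVolume:
    """Read a label stack written by :func:`write_labels`."""
    path = Path(path)
    arr = _read_stack(path)
    class_map = dict(DEFAULT_CLASS_MAP)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if voxel_size_um is None:
            voxel_size_um = meta.get("voxel_size_um")
        if "class_map" in meta:
            class_map = {int(k): v for k, v in meta["class_map"].items()}
    if voxel_size_um is None:
        raise ValueError(f"voxel size missing: pass voxel_size_um or provide sidecar {sidecar}")
    return LabelVolume(arr, class_map, float(voxel_size_um))
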