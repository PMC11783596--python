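"""Geometry-aware volume containers shared by every pipeline stage.

All world coordinates are millimetres in the DICOM LPS frame.  A voxel at
integer index ``i`` sits at the physical point

    x = origin + direction @ (spacing * i)

with 0-based indices.  Images, label maps, structure sets, dose grids and
displacement fields all carry the same :class:`ImageGeometry` so that
spatial operations can verify they are talking about the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

#: Canonical organ-at-risk roster (order fixes label indices 1..8).
CANONICAL_OARS: tuple[str, ...] = (
    "duodenum",
    "liver",
    "left_kidney",
    "right_kidney",
    "spleen",
    "stomach",
    "spinal_canal",
    "small_bowel",
)

_ORTHO_TOL = 1e-6


@dataclass(frozen=True)
class ImageGeometry:
    """Voxel grid geometry: size, spacing (mm), origin (mm), direction cosines."""

    size: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        size = tuple(int(s) for s in self.size)
        if len(size) != 3 or any(s <= 0 for s in size):
            raise ValueError(f"size must be 3 positive integers, got {self.size}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        origin = tuple(float(o) for o in self.origin)
        if len(origin) != 3:
            raise ValueError("origin must have 3 components")
        d = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.allclose(d.T @ d, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("direction matrix must be orthonormal")
        object.__setattr__(self, "size", size)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "direction", tuple(d.ravel()))

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float).reshape(3, 3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.size

    @property
    def _axis_aligned(self) -> bool:
        return self.direction == (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices (..., 3) to world mm (..., 3)."""
        idx = np.asarray(indices, dtype=float)
        scaled = idx * np.asarray(self.spacing)
        if self._axis_aligned:
            return scaled + np.asarray(self.origin)
        return scaled @ self.direction_matrix.T + np.asarray(self.origin)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world points (..., 3) in mm to continuous voxel indices (..., 3)."""
        pts = np.asarray(points, dtype=float) - np.asarray(self.origin)
        if self._axis_aligned:
            return pts / np.asarray(self.spacing)
        return (pts @ self.direction_matrix) / np.asarray(self.spacing)

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "ImageGeometry", tol: float = 1e-5) -> bool:
        return (
            self.size == other.size
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


def _require_same_grid(a: ImageGeometry, b: ImageGeometry, what: str) -> None:
    if not a.same_grid(b):
        raise ValueError(f"geometry mismatch: {what}")


@dataclass
class ScalarVolume:
    """Real-valued voxel array (image intensity, or dose in Gy) on a geometry."""

    geometry: ImageGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.geometry.size:
            raise ValueError(
                f"array shape {self.values.shape} != geometry size {self.geometry.size}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scalar volume contains non-finite values")

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.geometry, self.values.copy())


#: Alias used where the scalar grid carries absorbed dose in Gy.
DoseVolume = ScalarVolume


@dataclass
class LabelVolume:
    """Non-negative integer labels per voxel; 0 is background."""

    geometry: ImageGeometry
    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.shape != self.geometry.size:
            raise ValueError(
                f"array shape {arr.shape} != geometry size {self.geometry.size}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("label volume has non-integral values")
            arr = np.round(arr).astype(np.int64)
        if arr.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        if arr.max(initial=0) > 255:
            raise ValueError("more than 255 labels are not supported")
        self.labels = arr.astype(np.uint8)

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.geometry, self.labels.copy())


class StructureSet:
    """Ordered, named binary organ masks sharing one geometry.

    Masks are stored as boolean arrays.  Disjointness is an invariant of the
    *preprocessed* state, established by ``preprocess.resolve_overlaps``;
    the container itself allows overlap so that raw data can be loaded.
    """

    def __init__(
        self, geometry: ImageGeometry, structures: Mapping[str, np.ndarray]
    ) -> None:
        self.geometry = geometry
        self._masks: dict[str, np.ndarray] = {}
        for name, mask in structures.items():
            m = np.asarray(mask)
            if m.shape != geometry.size:
                raise ValueError(f"mask {name!r} shape {m.shape} != {geometry.size}")
            self._masks[str(name)] = m.astype(bool)

    # -- mapping-style access -------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._masks)

    def __len__(self) -> int:
        return len(self._masks)

    def __iter__(self) -> Iterator[str]:
        return iter(self._masks)

    def __contains__(self, name: str) -> bool:
        return name in self._masks

    def __getitem__(self, name: str) -> np.ndarray:
        return self._masks[name]

    def items(self):
        return self._masks.items()

    def copy(self) -> "StructureSet":
        return StructureSet(self.geometry, {n: m.copy() for n, m in self.items()})

    # -- invariants -----------------------------------------------------------
    def is_disjoint(self) -> bool:
        total = np.zeros(self.geometry.size, dtype=np.uint16)
        for mask in self._masks.values():
            total += mask
        return bool((total <= 1).all())

    def voxel_counts(self) -> dict[str, int]:
        return {n: int(m.sum()) for n, m in self.items()}


def labelmap_to_structures(lv: LabelVolume, names: Sequence[str]) -> StructureSet:
    """Split an integer label map into named binary masks (label k -> names[k-1])."""
    max_label = int(lv.labels.max(initial=0))
    if max_label > len(names):
        raise ValueError(
            f"label map contains label {max_label} but only {len(names)} names given"
        )
    return StructureSet(
        lv.geometry,
        {name: lv.labels == (k + 1) for k, name in enumerate(names)},
    )


def structures_to_labelmap(ss: StructureSet) -> LabelVolume:
    """Fuse disjoint masks into one label map (1-based in structure order)."""
    if not ss.is_disjoint():
        raise ValueError(
            "structures overlap; run preprocess.resolve_overlaps before fusing"
        )
    labels = np.zeros(ss.geometry.size, dtype=np.uint8)
    for k, (_, mask) in enumerate(ss.items(), start=1):
        labels[mask] = k
    return LabelVolume(ss.geometry, labels)
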