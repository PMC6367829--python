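"""Voxel grids, structure sets and deformation fields.

All volumes in a study live on one common grid with axis order
(LR, AP, IS): axis 0 increases toward patient left, axis 1 toward
anterior, axis 2 toward superior.  Coordinates are millimetres at voxel
centers; ``origin`` is the position of voxel (0, 0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

import numpy as np

AXES = ("LR", "AP", "IS")

# Nesting required of the target structures, innermost first.
TARGET_CHAIN = ("GTV", "CTV", "ITV", "PTV")
OAR_NAMES = ("liver", "kidney_L", "kidney_R", "spinal_cord", "bowel")


@dataclass
class VoxelGrid:
    """A 3D scalar volume (HU for images, dose otherwise) with geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar per voxel.
    spacing : tuple of float
        Voxel spacing in mm per axis (LR, AP, IS); strictly positive.
    origin : tuple of float
        Position (mm) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("VoxelGrid values must be 3-dimensional")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on all axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("VoxelGrid values must be finite")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def same_geometry(self, other: "VoxelGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def meshgrid_mm(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense voxel-center coordinates, one (nx, ny, nz) array per axis."""
        return tuple(
            np.meshgrid(
                self.axis_coords(0),
                self.axis_coords(1),
                self.axis_coords(2),
                indexing="ij",
            )
        )

    def mm_to_index(self, pts_mm: np.ndarray) -> np.ndarray:
        """Convert physical points (..., 3) to fractional voxel indices."""
        pts_mm = np.asarray(pts_mm, dtype=float)
        return (pts_mm - np.asarray(self.origin)) / np.asarray(self.spacing)

    def with_values(self, values: np.ndarray) -> "VoxelGrid":
        return VoxelGrid(values, self.spacing, self.origin)

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.values.copy(), self.spacing, self.origin)


@dataclass
class DeformationField:
    """Displacement field u(x) in mm on the reference (EEX) grid.

    ``displacement`` has shape (nx, ny, nz, 3) and maps reference
    positions to a breathing phase j: material at reference position x
    sits at x + u(x) during phase j.  Phase 0 is EEX and carries the
    zero field.
    """

    displacement: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    phase: int = 0

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[-1] != 3:
            raise ValueError("displacement must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacements must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.displacement.shape[:3]

    def is_zero(self, tol: float = 0.0) -> bool:
        return bool(np.max(np.abs(self.displacement)) <= tol)

    def scaled(self, factor: float) -> "DeformationField":
        return DeformationField(
            self.displacement * factor, self.spacing, self.origin, self.phase
        )


class StructureSet:
    """Named binary masks on the reference grid.

    Holds the nested target volumes (GTV ⊆ CTV ⊆ ITV ⊆ PTV) and the
    organs at risk.  Masks are boolean arrays with the reference shape.
    """

    def __init__(self, reference: VoxelGrid, masks: Dict[str, np.ndarray]):
        self.reference = reference
        self._masks: Dict[str, np.ndarray] = {}
        for name, mask in masks.items():
            self[name] = mask

    def __setitem__(self, name: str, mask: np.ndarray) -> None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.reference.shape:
            raise ValueError(
                f"mask {name!r} shape {mask.shape} != grid {self.reference.shape}"
            )
        self._masks[name] = mask

    def __getitem__(self, name: str) -> np.ndarray:
        return self._masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self._masks

    def __iter__(self) -> Iterator[str]:
        return iter(self._masks)

    def names(self) -> Tuple[str, ...]:
        return tuple(self._masks)

    def volume_cc(self, name: str) -> float:
        return float(self._masks[name].sum()) * self.reference.voxel_volume_cc

    def validate(self, require_all: bool = True) -> None:
        """Check nesting of targets and non-emptiness of every mask."""
        if require_all:
            for name in TARGET_CHAIN + OAR_NAMES:
                if name not in self._masks:
                    raise ValueError(f"missing structure {name!r}")
        for name, mask in self._masks.items():
            if not mask.any():
                raise ValueError(f"structure {name!r} is empty")
        chain = [n for n in TARGET_CHAIN if n in self._masks]
        for inner, outer in zip(chain, chain[1:]):
            if np.any(self._masks[inner] & ~self._masks[outer]):
                raise ValueError(f"{inner} not contained in {outer}")

    def centroid_mm(self, name: str) -> np.ndarray:
        """Center of mass of a mask in physical coordinates (mm)."""
        idx = np.argwhere(self._masks[name])
        if idx.size == 0:
            raise ValueError(f"structure {name!r} is empty")
        mean_idx = idx.mean(axis=0)
        return np.asarray(self.reference.origin) + mean_idx * np.asarray(
            self.reference.spacing
        )
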