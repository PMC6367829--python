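"""Synthetic abdominal phantom: HU volume plus target and OAR masks.

The phantom stands in for a pancreatic-cancer planning CT.  It is built
from geometric primitives in physical coordinates centered on the grid:
an elliptic soft-tissue body with a fat rim, a posterior vertebral
column enclosing the spinal cord, lateral-posterior kidneys, a
right-sided liver, an anterior bowel compartment and a central target
(pancreatic CTV) just anterior to the spine.

The CTV primitive is an ellipsoid whose radial scale is calibrated so
the voxelized volume matches the requested volume in cc.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np
from scipy import ndimage

from .grids import VoxelGrid, StructureSet


@dataclass
class PhantomConfig:
    """Geometry and tissue parameters of the synthetic patient.

    Positions and semi-axes are in mm relative to the grid center,
    axis order (LR, AP, IS); AP positive toward anterior.
    """

    shape: Tuple[int, int, int] = (96, 96, 96)
    spacing: Tuple[float, float, float] = (2.5, 2.5, 2.5)

    body_semiaxes: Tuple[float, float] = (78.0, 60.0)  # LR, AP
    fat_rim_mm: float = 8.0

    # vertebral column: bone cylinder along IS with embedded cord
    spine_center: Tuple[float, float] = (0.0, -42.0)
    spine_radius_mm: float = 13.0
    cord_radius_mm: float = 4.0

    ctv_center: Tuple[float, float, float] = (0.0, -4.0, 0.0)
    ctv_volume_cc: float = 51.9
    ctv_aspect: Tuple[float, float, float] = (1.3, 0.7, 1.5)
    gtv_scale: float = 0.75

    liver_center: Tuple[float, float, float] = (-40.0, 8.0, 28.0)
    liver_semiaxes: Tuple[float, float, float] = (30.0, 26.0, 34.0)
    kidney_centers: Tuple[Tuple[float, float, float], ...] = (
        (46.0, -26.0, -16.0),
        (-46.0, -26.0, -16.0),
    )
    kidney_semiaxes: Tuple[float, float, float] = (14.0, 12.0, 24.0)
    bowel_center: Tuple[float, float, float] = (6.0, 30.0, -12.0)
    bowel_semiaxes: Tuple[float, float, float] = (40.0, 20.0, 34.0)

    hu: Dict[str, float] = field(
        default_factory=lambda: {
            "air": -1000.0,
            "fat": -80.0,
            "soft": 40.0,
            "bone": 700.0,
            "cord": 30.0,
            "liver": 60.0,
            "kidney": 35.0,
            "bowel": -20.0,
            "ctv": 45.0,
        }
    )

    def grid_geometry(self) -> Tuple[Tuple[float, ...], Tuple[float, ...]]:
        """(spacing, origin) placing the physical origin at the grid center."""
        origin = tuple(
            -0.5 * (n - 1) * s for n, s in zip(self.shape, self.spacing)
        )
        return tuple(float(s) for s in self.spacing), origin


def _ellipsoid(coords, center, semiaxes) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    a, b, c = semiaxes
    return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0


def _calibrated_ctv_semiaxes(config: PhantomConfig, coords, voxel_cc: float):
    """Semi-axes whose voxelized ellipsoid volume best matches the target.

    Starts from the analytic solution 4/3*pi*abc = V and bisects a radial
    scale factor against the discrete voxel count.
    """
    r1, r2, r3 = config.ctv_aspect
    base = (3.0 * config.ctv_volume_cc * 1000.0 / (4.0 * np.pi * r1 * r2 * r3)) ** (
        1.0 / 3.0
    )

    def vox_volume(scale: float) -> float:
        semi = (scale * r1, scale * r2, scale * r3)
        return _ellipsoid(coords, config.ctv_center, semi).sum() * voxel_cc

    lo, hi = 0.9 * base, 1.1 * base
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if vox_volume(mid) < config.ctv_volume_cc:
            lo = mid
        else:
            hi = mid
    scale = 0.5 * (lo + hi)
    return (scale * r1, scale * r2, scale * r3)


def build_phantom(config: PhantomConfig) -> Tuple[VoxelGrid, StructureSet]:
    """Build the HU phantom and its structure set.

    Returns the CT grid and a :class:`StructureSet` with GTV/CTV and
    OARs; ITV and PTV are initialized to CTV and a 5 mm expansion and
    are meant to be replaced once breathing motion is known (see
    :func:`interplay4d.motion.derive_itv_ptv`).

    Raises
    ------
    ValueError
        If spacing is non-positive or the configured CTV overlaps the
        spinal cord.
    """
    if any(s <= 0 for s in config.spacing):
        raise ValueError("voxel spacing must be positive")
    spacing, origin = config.grid_geometry()
    grid = VoxelGrid(np.zeros(config.shape), spacing, origin)
    x, y, z = grid.meshgrid_mm()
    coords = (x, y, z)
    hu = config.hu

    body_out = (x / config.body_semiaxes[0]) ** 2 + (
        y / config.body_semiaxes[1]
    ) ** 2 <= 1.0
    ax_in = (
        config.body_semiaxes[0] - config.fat_rim_mm,
        config.body_semiaxes[1] - config.fat_rim_mm,
    )
    body_in = (x / ax_in[0]) ** 2 + (y / ax_in[1]) ** 2 <= 1.0

    values = np.full(config.shape, hu["air"])
    values[body_out] = hu["fat"]
    values[body_in] = hu["soft"]

    sx, sy = config.spine_center
    r2_spine = (x - sx) ** 2 + (y - sy) ** 2
    spine = r2_spine <= config.spine_radius_mm**2
    cord = r2_spine <= config.cord_radius_mm**2
    values[spine & body_in] = hu["bone"]
    values[cord & body_in] = hu["cord"]

    liver = _ellipsoid(coords, config.liver_center, config.liver_semiaxes) & body_in
    kid_L = _ellipsoid(coords, config.kidney_centers[0], config.kidney_semiaxes)
    kid_R = _ellipsoid(coords, config.kidney_centers[1], config.kidney_semiaxes)
    kid_L &= body_in & ~spine
    kid_R &= body_in & ~spine
    bowel = _ellipsoid(coords, config.bowel_center, config.bowel_semiaxes) & body_in

    ctv_semi = _calibrated_ctv_semiaxes(config, coords, grid.voxel_volume_cc)
    ctv = _ellipsoid(coords, config.ctv_center, ctv_semi) & body_in
    gtv = _ellipsoid(
        coords, config.ctv_center, tuple(config.gtv_scale * s for s in ctv_semi)
    )

    if np.any(ctv & (cord | spine)):
        raise ValueError("configured CTV overlaps the vertebral column/cord")

    # carve overlaps so organs do not claim target voxels
    for organ in (liver, kid_L, kid_R, bowel):
        organ &= ~ctv

    values[liver] = hu["liver"]
    values[kid_L] = hu["kidney"]
    values[kid_R] = hu["kidney"]
    values[bowel] = hu["bowel"]
    values[ctv] = hu["ctv"]

    # provisional targets before motion is known
    ptv = _dilate_mm(ctv, 5.0, spacing)
    structures = StructureSet(
        grid.with_values(values),
        {
            "GTV": gtv & ctv,
            "CTV": ctv,
            "ITV": ctv.copy(),
            "PTV": ptv,
            "liver": liver,
            "kidney_L": kid_L,
            "kidney_R": kid_R,
            "spinal_cord": cord & body_in,
            "bowel": bowel,
        },
    )
    structures.validate()
    return structures.reference, structures


def _dilate_mm(mask: np.ndarray, margin_mm: float, spacing) -> np.ndarray:
    """Isotropic dilation by a physical margin (ball in mm, not voxels)."""
    if margin_mm <= 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= margin_mm
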