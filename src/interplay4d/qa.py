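"""Deformation-field quality assurance.

Two checks mirror standard deformable-registration QA for 4D dose
pipelines: per-voxel Jacobian determinants of the EEX-to-EIN field
inside the organ-at-risk delineations (volume conservation), and the
mass ratio m_EEX / m_EIN obtained by warping each OAR delineation to
end-inhalation and multiplying volumes by HU-derived densities (mass
conservation).  Intensity warping does not conserve mass in general;
the ratio quantifies by how much.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .density import HuDensityTable
from .grids import DeformationField, VoxelGrid

QA_OARS = ("liver", "kidney_L", "kidney_R", "bowel")


def jacobian_determinant_map(dvf: DeformationField) -> VoxelGrid:
    """Per-voxel det(I + grad u) of a displacement field.

    Gradients are central finite differences in physical mm; one-sided
    at the grid boundary (``np.gradient`` convention).  A value of 1
    means locally volume-preserving; values <= 0 indicate folding.
    """
    u = dvf.displacement
    jac = np.empty(dvf.shape + (3, 3))
    for comp in range(3):
        grads = np.gradient(u[..., comp], *dvf.spacing, edge_order=1)
        for axis in range(3):
            jac[..., comp, axis] = grads[axis]
    jac[..., 0, 0] += 1.0
    jac[..., 1, 1] += 1.0
    jac[..., 2, 2] += 1.0
    det = np.linalg.det(jac)
    return VoxelGrid(det, dvf.spacing, dvf.origin)


def mass_conservation_ratio(
    ct_eex: VoxelGrid,
    dvf_eex_to_ein: DeformationField,
    mask_eex: np.ndarray,
    table: Optional[HuDensityTable] = None,
) -> float:
    """Mass ratio m_EEX / m_EIN for one delineation.

    m_EEX sums voxel volume times density over the EEX delineation;
    m_EIN does the same over the delineation warped to EIN, with
    densities taken from the correspondingly warped image, so mask and
    anatomy move together.  An identity field returns exactly 1.0.
    """
    if table is None:
        table = HuDensityTable()
    if not mask_eex.any():
        raise ValueError("EEX mask is empty")
    voxel_cc = ct_eex.voxel_volume_cc
    rho_eex = table(ct_eex.values[mask_eex])
    m_eex = voxel_cc * float(rho_eex.sum())

    if dvf_eex_to_ein.is_zero():
        return 1.0

    from .motion import _forward_coords

    coords = _forward_coords(dvf_eex_to_ein)
    mask_ein = (
        ndimage.map_coordinates(
            mask_eex.astype(np.float32), coords, order=1, mode="constant", cval=0.0
        )
        >= 0.5
    )
    if not mask_ein.any():
        raise ValueError("warped mask is empty")
    hu_ein = ndimage.map_coordinates(
        ct_eex.values.astype(float), coords, order=1, mode="constant", cval=-1000.0
    )
    m_ein = voxel_cc * float(table(hu_ein[mask_ein]).sum())
    return m_eex / m_ein


@dataclass
class QaReport:
    """Per-OAR Jacobian statistics and mass-conservation ratios."""

    rows: pd.DataFrame  # columns: organ, mean_jacobian, sd_jacobian,
    #          min_jacobian, n_folding, mass_ratio, v_eex_cc, v_ein_cc

    @property
    def mean_jacobian(self) -> float:
        return float(self.rows["mean_jacobian"].mean())

    @property
    def mean_mass_ratio(self) -> float:
        return float(self.rows["mass_ratio"].mean())

    @property
    def has_folding(self) -> bool:
        return bool((self.rows["n_folding"] > 0).any())

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False, float_format="%.6g")


def qa_report(
    ct_eex: VoxelGrid,
    structures,
    motions,
    table: Optional[HuDensityTable] = None,
    oars: Sequence[str] = QA_OARS,
) -> QaReport:
    """QA of the EEX-to-EIN field of each motion input over the OAR set.

    For every motion input, Jacobian determinants are evaluated inside
    each OAR delineation and the mass ratio computed; voxels with
    det J <= 0 are counted as folding.
    """
    if table is None:
        table = HuDensityTable()
    from .motion import MotionInput

    if isinstance(motions, MotionInput):
        motions = [motions]
    records = []
    for motion in motions:
        dvf = motion.field(motion.ein_phase)
        det = jacobian_determinant_map(dvf).values
        for organ in oars:
            mask = structures[organ]
            vals = det[mask]
            ratio = mass_conservation_ratio(ct_eex, dvf, mask, table)
            records.append(
                {
                    "motion_id": motion.motion_id,
                    "organ": organ,
                    "mean_jacobian": float(vals.mean()),
                    "sd_jacobian": float(vals.std()),
                    "min_jacobian": float(vals.min()),
                    "n_folding": int((vals <= 0).sum()),
                    "mass_ratio": float(ratio),
                    "v_eex_cc": float(mask.sum()) * ct_eex.voxel_volume_cc,
                }
            )
    return QaReport(pd.DataFrame.from_records(records))
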