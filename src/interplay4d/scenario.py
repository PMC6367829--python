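"""The patient scenario: anatomy, motion inputs and prescription."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

from .grids import StructureSet, VoxelGrid
from .motion import MotionInput
from .planning import Prescription


@dataclass
class PatientScenario:
    """Reference anatomy plus the available breathing measurements.

    ``gantry_angles_deg`` follows the two-posterior-oblique (160/210)
    or two-anterior (20/340) beam arrangements used for pancreatic
    targets; angles live in [0, 360).
    """

    patient_id: str
    ct: VoxelGrid
    structures: StructureSet
    motions: List[MotionInput]
    gantry_angles_deg: Tuple[float, float] = (160.0, 210.0)
    prescription: Prescription = field(default_factory=Prescription)

    def __post_init__(self) -> None:
        if len(self.motions) < 1:
            raise ValueError("scenario needs at least one motion input")
        for a in self.gantry_angles_deg:
            if not (0.0 <= a < 360.0):
                raise ValueError("gantry angles must be in [0, 360)")

    @property
    def n_measurements(self) -> int:
        """Number of measured-analog motion inputs (correlation weights)."""
        return sum(1 for m in self.motions if m.measured)

    def motion_ids(self) -> List[str]:
        return [m.motion_id for m in self.motions]
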