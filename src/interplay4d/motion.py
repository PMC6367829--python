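"""Breathing motion: periodic deformation fields and motion-derived targets.

One "motion input" emulates a single repeated 4D acquisition of a
patient: 20 breathing phases, uniform in time over one cycle of period
T, each phase a displacement field w.r.t. the end-exhalation reference
(EEX, phase 0).  The generated fields are separable,

    u(x, j) = envelope(x) * f_j * a,

with a smooth spatial envelope equal to 1 at a focus point (the CTV
centroid), decaying to zero toward the posterior spine and the grid
boundary; f_j = sin^2(pi j / 20) the default regular-breathing temporal
factor (maximal at phase 10, EIN); and a the signed amplitude vector in
mm.  The separable form is exploited by the 4D dose engine to evaluate
fields cheaply at arbitrary points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from .grids import DeformationField, VoxelGrid
from .phantom import _dilate_mm

PERIOD_RANGE_S = (2.8, 10.0)
N_PHASES = 20
AIR_HU = -1000.0


@dataclass(frozen=True)
class Amplitudes:
    """Peak (EIN-EEX) CTV-centroid displacement per axis, in mm (magnitudes)."""

    is_mm: float = 8.0
    ap_mm: float = 3.0
    lr_mm: float = 2.0

    def as_vector(self, signs: Tuple[float, float, float] = (1.0, 1.0, -1.0)):
        """Signed displacement vector in (LR, AP, IS) axis order.

        Default signs: toward patient left, anterior, and inferior at
        inhalation (abdominal organs are pushed down by the diaphragm).
        """
        return np.array(
            [signs[0] * self.lr_mm, signs[1] * self.ap_mm, signs[2] * self.is_mm]
        )


def sin2_temporal_factors(n_phases: int = N_PHASES) -> np.ndarray:
    """Regular-breathing temporal factor sin^2(pi j / n), zero at phase 0."""
    j = np.arange(n_phases)
    return np.sin(np.pi * j / n_phases) ** 2


@dataclass
class MotionInput:
    """One breathing measurement: 20 phase fields plus the cycle period.

    Attributes
    ----------
    motion_id : str
        Identifier in the style m1, m2, ...
    period_s : float
        Breathing period T in seconds, within [2.8, 10].
    envelope : ndarray (nx, ny, nz)
        Spatial modulation, 1 at the focus, in [0, 1].
    temporal : ndarray (n_phases,)
        Per-phase temporal factor, 0 at phase 0.
    direction_mm : ndarray (3,)
        Signed peak displacement vector (LR, AP, IS) in mm.
    measured : bool
        True for a measured-analog pattern, False for a period-rescaled
        variant of another measurement.
    """

    motion_id: str
    period_s: float
    envelope: np.ndarray
    temporal: np.ndarray
    direction_mm: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float]
    measured: bool = True
    source_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (PERIOD_RANGE_S[0] <= self.period_s <= PERIOD_RANGE_S[1]):
            raise ValueError(
                f"period {self.period_s} s outside {PERIOD_RANGE_S}"
            )
        self.temporal = np.asarray(self.temporal, dtype=float)
        if self.temporal.shape[0] != N_PHASES:
            raise ValueError(f"exactly {N_PHASES} phases required")
        if self.temporal[0] != 0.0:
            raise ValueError("phase 0 (EEX) must carry the zero field")
        self.envelope = np.asarray(self.envelope, dtype=np.float32)
        self.direction_mm = np.asarray(self.direction_mm, dtype=float)

    @property
    def n_phases(self) -> int:
        return int(self.temporal.shape[0])

    @property
    def ein_phase(self) -> int:
        """Phase of maximal displacement (end-inhalation)."""
        return int(np.argmax(self.temporal))

    def displacement(self, phase: int) -> np.ndarray:
        """Displacement array (nx, ny, nz, 3) in mm for one phase."""
        return (
            self.envelope[..., None].astype(float)
            * self.temporal[phase]
            * self.direction_mm
        )

    def field(self, phase: int) -> DeformationField:
        return DeformationField(
            self.displacement(phase), self.spacing, self.origin, phase=phase
        )

    @property
    def fields(self) -> List[DeformationField]:
        return [self.field(j) for j in range(self.n_phases)]

    @property
    def peak_amplitude_mm(self) -> np.ndarray:
        """|EIN-EEX| displacement magnitudes per axis at the focus (LR, AP, IS)."""
        return np.abs(self.direction_mm) * self.temporal[self.ein_phase]


def _half_cosine_window(coords: np.ndarray, lo: float, focus: float, hi: float):
    """Window that is 0 at ``lo`` and ``hi``, 1 at ``focus``, C1-smooth."""
    w = np.zeros_like(coords, dtype=float)
    rising = (coords > lo) & (coords < focus)
    t = (coords[rising] - lo) / max(focus - lo, 1e-9)
    w[rising] = 0.5 - 0.5 * np.cos(np.pi * t)
    falling = (coords >= focus) & (coords < hi)
    t = (hi - coords[falling]) / max(hi - focus, 1e-9)
    w[falling] = 0.5 - 0.5 * np.cos(np.pi * t)
    return w


def motion_envelope(
    grid: VoxelGrid,
    focus_mm: Sequence[float],
    posterior_zero_mm: float = -28.0,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Smooth spatial envelope: 1 at the focus, 0 at spine and boundary.

    The AP window vanishes for all y <= ``posterior_zero_mm`` so the
    vertebral column and spinal cord stay static.  An optional seed
    shrinks the window support by up to 25% per side to emulate
    day-to-day variation of the motion pattern shape without changing
    the focus amplitude.
    """
    rng = np.random.default_rng(seed) if seed is not None else None

    def jitter() -> float:
        return float(rng.uniform(0.75, 1.0)) if rng is not None else 1.0

    x = grid.axis_coords(0)
    y = grid.axis_coords(1)
    z = grid.axis_coords(2)
    fx, fy, fz = (float(v) for v in focus_mm)

    wx = _half_cosine_window(
        x, fx - (fx - x[0]) * jitter(), fx, fx + (x[-1] - fx) * jitter()
    )
    y_lo = max(posterior_zero_mm, y[0])
    wy = _half_cosine_window(
        y, fy - (fy - y_lo) * jitter(), fy, fy + (y[-1] - fy) * jitter()
    )
    wz = _half_cosine_window(
        z, fz - (fz - z[0]) * jitter(), fz, fz + (z[-1] - fz) * jitter()
    )
    return (wx[:, None, None] * wy[None, :, None] * wz[None, None, :]).astype(
        np.float32
    )


def generate_motion_input(
    grid: VoxelGrid,
    amplitudes: Amplitudes,
    period_s: float,
    focus_mm: Sequence[float],
    motion_id: str = "m1",
    n_phases: int = N_PHASES,
    temporal: Optional[np.ndarray] = None,
    posterior_zero_mm: float = -28.0,
    seed: Optional[int] = None,
    measured: bool = True,
) -> MotionInput:
    """Generate one breathing measurement on the reference grid.

    The focus (normally the CTV centroid) reaches exactly the requested
    per-axis amplitudes at end-inhalation.  Raises ``ValueError`` if the
    requested amplitude would fold space (non-positive Jacobian
    determinant of the EIN field).
    """
    if amplitudes.is_mm < 0 or amplitudes.ap_mm < 0 or amplitudes.lr_mm < 0:
        raise ValueError("amplitudes must be non-negative")
    if temporal is None:
        temporal = sin2_temporal_factors(n_phases)
    envelope = motion_envelope(grid, focus_mm, posterior_zero_mm, seed=seed)
    motion = MotionInput(
        motion_id=motion_id,
        period_s=period_s,
        envelope=envelope,
        temporal=np.asarray(temporal, dtype=float),
        direction_mm=amplitudes.as_vector(),
        spacing=grid.spacing,
        origin=grid.origin,
        measured=measured,
    )
    if np.any(np.abs(motion.direction_mm) > 0):
        from .qa import jacobian_determinant_map

        det = jacobian_determinant_map(motion.field(motion.ein_phase))
        dmin = float(det.values.min())
        if dmin <= 0.05:
            raise ValueError(
                f"requested amplitude folds the deformation (min det J = {dmin:.3f});"
                " reduce amplitude or widen the envelope"
            )
    return motion


def rescale_period(motion: MotionInput, new_period_s: float) -> MotionInput:
    """Variant of a measurement with only the breathing period changed.

    Displacement fields are shared untouched (amplitudes are kept fixed
    when the cycle length is varied); the result is marked as a
    rescaled, non-measured variant of its source.
    """
    if not (PERIOD_RANGE_S[0] <= new_period_s <= PERIOD_RANGE_S[1]):
        raise ValueError(f"period {new_period_s} s outside {PERIOD_RANGE_S}")
    source = motion.source_id or motion.motion_id
    return replace(
        motion,
        period_s=float(new_period_s),
        measured=False,
        source_id=source,
        motion_id=f"{motion.motion_id}@T{new_period_s:g}",
    )


# ---------------------------------------------------------------------------
# warping


def _pullback_coords(dvf: DeformationField) -> np.ndarray:
    idx = np.indices(dvf.shape, dtype=float)
    disp_vox = np.moveaxis(dvf.displacement, -1, 0) / np.asarray(dvf.spacing)[
        :, None, None, None
    ]
    return idx + disp_vox


def warp_image(
    image: VoxelGrid,
    dvf: DeformationField,
    fill_value: float = AIR_HU,
    order: int = 1,
) -> VoxelGrid:
    """Pull the reference image to a breathing phase.

    Output voxel value = input interpolated at (reference position +
    displacement); samples outside the grid take ``fill_value`` (air HU
    by default).
    """
    if image.shape != dvf.shape:
        raise ValueError("image and deformation field are on different grids")
    if dvf.is_zero():
        return image.copy()
    warped = ndimage.map_coordinates(
        image.values.astype(float),
        _pullback_coords(dvf),
        order=order,
        mode="constant",
        cval=fill_value,
    )
    return image.with_values(warped)


def _forward_coords(dvf: DeformationField) -> np.ndarray:
    """Sampling coordinates of the first-order inverse (push-forward) warp."""
    idx = np.indices(dvf.shape, dtype=float)
    disp_vox = np.moveaxis(dvf.displacement, -1, 0) / np.asarray(dvf.spacing)[
        :, None, None, None
    ]
    return idx - disp_vox


def warp_mask_forward(mask: np.ndarray, dvf: DeformationField) -> np.ndarray:
    """Push a binary mask along the material motion (EEX -> phase).

    Material at reference x sits at x + u(x) in the phase, so the warped
    mask is sampled at x - u(x) (first-order inverse), trilinear with a
    0.5 threshold (ties toward inclusion); the trilinear boundary avoids
    the lattice bias of nearest-neighbour warping.  Under an expanding
    field (det J > 1) the mask volume grows accordingly.
    """
    if mask.shape != dvf.shape:
        raise ValueError("mask and deformation field are on different grids")
    if dvf.is_zero():
        return mask.copy()
    warped = ndimage.map_coordinates(
        mask.astype(np.float32),
        _forward_coords(dvf),
        order=1,
        mode="constant",
        cval=0.0,
    )
    return warped >= 0.5


def phase_image(
    ct: VoxelGrid, motion: MotionInput, phase: int, fill_value: float = AIR_HU
) -> VoxelGrid:
    """Synthetic phase CT: anatomy carried along the material motion.

    Material at reference x sits at x + u(x) in the phase, so the phase
    image samples the reference CT at x - u(x) (first-order inverse of
    the displacement).  This keeps the deformed anatomy, the warped
    delineations and the 4D dose accumulation on the same side of the
    motion; :func:`warp_image` remains the generic pull-back resampler.
    """
    dvf = motion.field(phase)
    if dvf.is_zero():
        return ct.copy()
    warped = ndimage.map_coordinates(
        ct.values.astype(float),
        _forward_coords(dvf),
        order=1,
        mode="constant",
        cval=fill_value,
    )
    return ct.with_values(warped)


def derive_itv_ptv(
    ctv: np.ndarray,
    motions: Union[MotionInput, Iterable[MotionInput]],
    spacing: Tuple[float, float, float],
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0),
    margin_mm: float = 5.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """ITV as the union of the CTV over all breathing phases, plus PTV.

    The CTV is carried to every phase of every given motion input and
    the union taken on the reference grid; the PTV adds an isotropic
    physical margin (ball in mm) around the ITV.
    """
    if not ctv.any():
        raise ValueError("CTV mask is empty")
    if isinstance(motions, MotionInput):
        motions = [motions]
    itv = ctv.copy()
    for motion in motions:
        for j in range(motion.n_phases):
            if motion.temporal[j] == 0.0:
                continue
            itv |= warp_mask_forward(ctv, motion.field(j))
    ptv = _dilate_mm(itv, margin_mm, spacing)
    return itv, ptv
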