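"""Time-resolved (4D) dose calculation with breathing interplay.

Each spot's start timestamp, the breathing period T of the active
motion input and the field's initial breathing phase determine the
phase in which the spot is delivered:

    phase(t) = (start_phase + floor(n_phases * t / T)) mod n_phases,

with phase bins uniform in time.  The spots of one phase deposit their
dose on that phase's deformed geometry (WEPL re-traced on the warped
CT); the phase dose is then pulled back to the reference frame by
sampling at x + u_j(x), and the fraction dose is the sum over phases
and both fields.

The engine memoizes per (motion, field, start phase): with 20 phases
there are only 20 distinct per-field doses per motion input, so
arbitrarily many simulated fractions reuse a small set of dose grids.
CTV-restricted dose vectors are cached separately from full grids,
which keeps fractionation studies cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .beam import BeamFrame, BeamGeometry
from .density import HuDensityTable
from .grids import VoxelGrid
from .machine import MachineModel
from .metrics import metrics_from_values
from .motion import MotionInput
from .planning import SpotPlan, field_frame

N_PHASES = 20


def assign_spots_to_phases(
    timestamps: np.ndarray,
    period_s: float,
    start_phase: int,
    n_phases: int = N_PHASES,
) -> np.ndarray:
    """Breathing phase index of each spot from its start timestamp."""
    if period_s <= 0:
        raise ValueError("period must be positive")
    if not 0 <= start_phase < n_phases:
        raise ValueError("start phase out of range")
    t = np.asarray(timestamps, dtype=float)
    return (start_phase + np.floor(n_phases * t / period_s).astype(int)) % n_phases


@dataclass(frozen=True)
class StartingPhasePair:
    """Initial breathing phases (i, k) of fields F0 and F1."""

    i: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.i < N_PHASES and 0 <= self.k < N_PHASES):
            raise ValueError("starting phases must be in 0..19")


@dataclass
class FractionDose:
    """One fraction's reference-frame dose with its provenance."""

    motion_id: str
    phases: StartingPhasePair
    ctv_dose: np.ndarray  # % of fraction prescription, CTV voxels
    dose: Optional[VoxelGrid] = None  # full grid, on request


class InterplayEngine:
    """4D dose calculator for one (normalized, timed) plan and scenario.

    Parameters
    ----------
    plan : SpotPlan
        Normalized plan with delivery timestamps.
    ct : VoxelGrid
        Reference (EEX) CT.
    structures : StructureSet
        Must contain the CTV; metrics vectors are CTV-restricted.
    motions : sequence of MotionInput
        Available breathing measurements, keyed by ``motion_id``.
    """

    def __init__(
        self,
        plan: SpotPlan,
        ct: VoxelGrid,
        structures,
        motions: Sequence[MotionInput],
        machine: Optional[MachineModel] = None,
        table: Optional[HuDensityTable] = None,
    ):
        for f in plan.fields:
            if f.timestamps is None:
                raise ValueError("plan needs delivery timestamps (delivery_timeline)")
        self.plan = plan
        self.ct = ct
        self.structures = structures
        self.machine = machine or MachineModel()
        self.table = table or HuDensityTable()
        self.motions: Dict[str, MotionInput] = {m.motion_id: m for m in motions}

        self.ctv_mask = structures["CTV"]
        self._ctv_idx = np.argwhere(self.ctv_mask)
        ctv_pts = np.asarray(ct.origin) + self._ctv_idx * np.asarray(ct.spacing)

        self._frames: List[BeamFrame] = []
        self._geoms: List[BeamGeometry] = []
        self._ctv_base: List[np.ndarray] = []  # (3, n_ctv) beam indices
        self._proj: List[Dict[str, np.ndarray]] = []
        self._env_beam: Dict[Tuple[str, int], np.ndarray] = {}
        self._env_ctv: Dict[str, np.ndarray] = {}
        self._wepl_cache: Dict[Tuple[str, int, float], np.ndarray] = {}
        self._ctv_dose_cache: Dict[Tuple[str, int, int], np.ndarray] = {}
        self._full_dose_cache: Dict[Tuple[str, int, int], np.ndarray] = {}
        self._full_base: List[np.ndarray] = []
        self._lat_cache: Dict[Tuple[int, float], list] = {}
        self._depth_cache: Dict[Tuple[str, int, float, float], np.ndarray] = {}

        x, y, z = ct.meshgrid_mm()
        grid_pts = np.stack([x, y, z], axis=-1)
        for f in plan.fields:
            geom = BeamGeometry(f.gantry_angle_deg)
            frame = field_frame(ct, f, geom)
            self._geoms.append(geom)
            self._frames.append(frame)
            self._ctv_base.append(
                np.ascontiguousarray(
                    np.moveaxis(frame.bev_to_index(geom.to_bev(ctv_pts)), -1, 0)
                )
            )
            self._full_base.append(
                np.moveaxis(frame.bev_to_index(geom.to_bev(grid_pts)), -1, 0)
            )

    # ------------------------------------------------------------------
    # cached geometry pieces

    def _motion(self, m_id: str) -> MotionInput:
        try:
            return self.motions[m_id]
        except KeyError:
            raise KeyError(f"unknown motion input {m_id!r}") from None

    def _gid(self, m_id: str) -> str:
        """Geometry key: period-rescaled variants share their source's
        displacement fields, so their caches are shared too."""
        m = self._motion(m_id)
        return m.source_id or m.motion_id

    def _envelope_beam(self, m_id: str, fi: int) -> np.ndarray:
        key = (self._gid(m_id), fi)
        if key not in self._env_beam:
            env = self._motion(m_id).envelope
            self._env_beam[key] = self._frames[fi].sample_patient_values(
                env, cval=0.0
            )
        return self._env_beam[key]

    def _envelope_ctv(self, m_id: str) -> np.ndarray:
        gid = self._gid(m_id)
        if gid not in self._env_ctv:
            env = self._motion(m_id).envelope
            self._env_ctv[gid] = env[self.ctv_mask].astype(float)
        return self._env_ctv[gid]

    def _phase_wepl(self, m_id: str, fi: int, factor: float) -> np.ndarray:
        """WEPL on the phase geometry; keyed by the temporal factor so
        symmetric phases (sin^2 is mirror-symmetric) share one entry."""
        if factor == 0.0:
            key = ("__static__", fi, 0.0)  # phase 0 is motion-independent
        else:
            key = (self._gid(m_id), fi, round(float(factor), 12))
        if key not in self._wepl_cache:
            frame = self._frames[fi]
            if factor == 0.0:
                density = self.table(frame.sample_patient_values(self.ct.values))
            else:
                # anatomy at reference x sits at x + u(x) in this phase, so
                # the phase CT is the push-forward warp, sampled at x - u(x)
                motion = self._motion(m_id)
                shift_mm = -factor * motion.direction_mm
                env = self._envelope_beam(m_id, fi)
                shift_idx = np.stack(
                    [env * (shift_mm[c] / self.ct.spacing[c]) for c in range(3)]
                )
                density = self.table(
                    frame.sample_patient_values(self.ct.values, shift_index=shift_idx)
                )
            self._wepl_cache[key] = frame.wepl_from_density(density).astype(
                np.float32
            )
        return self._wepl_cache[key]

    # ------------------------------------------------------------------
    # per-field 4D doses

    def _delivery_groups(self, fi: int, period_s: float) -> list:
        """Start-phase-independent delivery segments of one field.

        Spots are grouped by (energy layer, delivery time bin mod 20):
        for starting phase i a group with bin b is delivered entirely
        in breathing phase (i + b) mod 20.  Each group's lateral dose
        field (Fourier synthesis, sigma from the static slice-mean
        WEPL) is precomputed once per (field, period) and reused for
        every starting phase and motion input sharing that period.
        """
        key = (fi, round(float(period_s), 9))
        if key in self._lat_cache:
            return self._lat_cache[key]
        f = self.plan.fields[fi]
        frame = self._frames[fi]
        nu, nv, ns = frame.shape
        pad = 8
        pu, pv = nu + pad, nv + pad
        kx = 2.0 * np.pi * np.fft.fftfreq(pu, d=frame.step)
        ky = 2.0 * np.pi * np.fft.fftfreq(pv, d=frame.step)
        k2 = kx[:, None] ** 2 + ky[None, :] ** 2

        wepl0 = self._phase_wepl("__static__", fi, 0.0)
        wmin_col = np.asarray(wepl0.min(axis=(0, 1)), dtype=float)
        sigma_s = np.asarray(self.machine.sigma_mm(wepl0.mean(axis=(0, 1))))
        kern_full = np.exp(-0.5 * sigma_s[:, None, None] ** 2 * k2[None, :, :])

        bins = np.floor(N_PHASES * f.timestamps / period_s).astype(int) % N_PHASES
        inv_area = 1.0 / (frame.step * frame.step)
        groups = []
        for layer in np.unique(f.layers):
            sel_l = f.layers == layer
            e = float(f.energies[sel_l][0])
            r = float(self.machine.range_mm(e))
            stop = r + 4.0 * self.machine.range_sigma_mm(r)
            s_cut = min(int(np.searchsorted(wmin_col, stop)) + 1, ns)
            for b in np.unique(bins[sel_l]):
                sel = sel_l & (bins == b)
                phase_fac = np.exp(
                    -1j
                    * (
                        kx[:, None, None] * (f.u_mm[sel] - frame.u[0])[None, None, :]
                        + ky[None, :, None] * (f.v_mm[sel] - frame.v[0])[None, None, :]
                    )
                )
                s_hat = (phase_fac * f.weights[sel][None, None, :]).sum(axis=2)
                field = np.fft.ifft2(
                    kern_full[:s_cut] * s_hat[None, :, :], axes=(1, 2)
                ).real
                lat = np.moveaxis(field[:, :nu, :nv], 0, 2) * inv_area
                groups.append((int(b), e, s_cut, lat.astype(np.float32)))
        self._lat_cache[key] = groups
        return groups

    def _depth_factor(
        self, m_id: str, fi: int, factor: float, energy: float, s_cut: int
    ) -> np.ndarray:
        """Cached per-voxel Bragg depth dose on the phase geometry."""
        key = (self._gid(m_id) if factor != 0.0 else "__static__", fi,
               round(float(factor), 12), round(energy, 6), s_cut)
        if key not in self._depth_cache:
            wepl = self._phase_wepl(m_id, fi, factor)
            self._depth_cache[key] = self.machine.bragg_depth_dose(
                energy, np.asarray(wepl[:, :, :s_cut], dtype=float)
            ).astype(np.float32)
        return self._depth_cache[key]

    def field_dose_4d(
        self, m_id: str, fi: int, start_phase: int, full: bool = False
    ) -> np.ndarray:
        """One field's 4D dose for a motion input and starting phase.

        Returns the CTV-voxel dose vector, or the full reference-frame
        grid when ``full`` is set; both are cached.
        """
        key = (m_id, fi, int(start_phase))
        cache = self._full_dose_cache if full else self._ctv_dose_cache
        if key in cache:
            return cache[key]
        frame = self._frames[fi]
        motion = self._motion(m_id)
        groups = self._delivery_groups(fi, motion.period_s)

        # accumulate the beam-frame dose of every breathing phase
        beams: Dict[int, np.ndarray] = {}
        for b, e, s_cut, lat in groups:
            j = (start_phase + b) % N_PHASES
            factor = float(motion.temporal[j])
            depth = self._depth_factor(m_id, fi, factor, e, s_cut)
            buf = beams.get(j)
            if buf is None:
                buf = beams[j] = np.zeros(frame.shape)
            buf[:, :, :s_cut] += depth * lat

        if full:
            out = np.zeros(self.ct.shape)
            base = self._full_base[fi]
            env = motion.envelope.astype(float)
        else:
            out = np.zeros(self._ctv_idx.shape[0])
            base = self._ctv_base[fi]
            env = self._envelope_ctv(m_id)

        geom = self._geoms[fi]
        proj = np.array(
            [
                motion.direction_mm @ geom.u_axis,
                motion.direction_mm @ geom.v_axis,
                motion.direction_mm @ geom.direction,
            ]
        )
        for j, dose_beam in beams.items():
            factor = float(motion.temporal[j])
            if factor == 0.0 or not np.any(proj):
                coords = base
            else:
                shift = (factor / frame.step) * proj
                coords = base + env[None, ...] * shift.reshape(
                    (3,) + (1,) * env.ndim
                )
            out += ndimage.map_coordinates(
                dose_beam, coords, order=1, mode="constant", cval=0.0
            )
        cache[key] = out
        return out

    def compute_4d_dose(
        self, m_id: str, phases: StartingPhasePair, full: bool = False
    ) -> FractionDose:
        """One fraction's 4D dose for motion ``m_id`` and phases (i, k)."""
        ctv = self.field_dose_4d(m_id, 0, phases.i) + self.field_dose_4d(
            m_id, 1, phases.k
        )
        dose = None
        if full:
            grid = self.field_dose_4d(m_id, 0, phases.i, full=True) + (
                self.field_dose_4d(m_id, 1, phases.k, full=True)
            )
            dose = self.ct.with_values(grid)
        return FractionDose(m_id, phases, ctv, dose)

    # ------------------------------------------------------------------
    # static reference through the same numerical path

    def static_ctv_dose(self) -> np.ndarray:
        """Static (3DDC) CTV dose vector via the identical engine path."""
        out = np.zeros(self._ctv_idx.shape[0])
        for fi, f in enumerate(self.plan.fields):
            wepl = self._phase_wepl("__static__", fi, 0.0)
            dose_beam = self._frames[fi].deposit_layers_fft(
                wepl, f.energies, f.u_mm, f.v_mm, f.weights, self.machine
            )
            out += ndimage.map_coordinates(
                dose_beam, self._ctv_base[fi], order=1, mode="constant", cval=0.0
            )
        return out

    def static_dose(self) -> VoxelGrid:
        total = np.zeros(self.ct.shape)
        for fi, f in enumerate(self.plan.fields):
            wepl = self._phase_wepl("__static__", fi, 0.0)
            dose_beam = self._frames[fi].deposit_layers_fft(
                wepl, f.energies, f.u_mm, f.v_mm, f.weights, self.machine
            )
            total += ndimage.map_coordinates(
                dose_beam, self._full_base[fi], order=1, mode="constant", cval=0.0
            )
        return self.ct.with_values(total)

    def clear_caches(self) -> None:
        self._wepl_cache.clear()
        self._ctv_dose_cache.clear()
        self._full_dose_cache.clear()
        self._env_beam.clear()
        self._lat_cache.clear()
        self._depth_cache.clear()

    def release_motion(self, m_id: str) -> None:
        """Drop the heavy per-motion geometry caches, keeping dose vectors."""
        gid = self._gid(m_id) if m_id in self.motions else m_id
        for cache in (self._wepl_cache, self._depth_cache):
            for key in [k for k in cache if k[0] == gid]:
                del cache[key]
        for key in [k for k in self._env_beam if k[0] == gid]:
            del self._env_beam[key]


def enumerate_single_fraction(
    engine: InterplayEngine,
    m_ids: Optional[Iterable[str]] = None,
    mode: str = "grid",
) -> pd.DataFrame:
    """The 4Dx1 ensemble: CTV metrics over starting-phase combinations.

    ``mode='grid'`` combines all 20 x 20 per-field starting phases
    (i, k); ``mode='diagonal'`` uses the 20 pairs with i = k.  Returns
    one row per ensemble member with columns m, i, k and the CTV metric
    set.
    """
    if m_ids is None:
        m_ids = list(engine.motions)
    if mode == "grid":
        pairs = [(i, k) for i in range(N_PHASES) for k in range(N_PHASES)]
    elif mode == "diagonal":
        pairs = [(i, i) for i in range(N_PHASES)]
    else:
        raise ValueError("mode must be 'grid' or 'diagonal'")
    rows = []
    for m_id in m_ids:
        for i, k in pairs:
            vec = engine.field_dose_4d(m_id, 0, i) + engine.field_dose_4d(m_id, 1, k)
            row = {"m": m_id, "i": i, "k": k}
            row.update(metrics_from_values(vec))
            rows.append(row)
    return pd.DataFrame(rows)
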