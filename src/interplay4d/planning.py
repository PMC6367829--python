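"""SFUD spot planning, weight optimization and delivery time structure.

Each of the two fields is optimized independently to deliver a uniform
half-prescription dose to the PTV (single-field uniform dose).  Spots
sit on a regular lateral grid in the beam's eye view and on energy
layers spaced uniformly in WEPL; non-negative weights are found by
multiplicative (MLEM-style) updates, which preserve positivity and are
exactly linear in the prescription.  The timeline assigns each spot a
start time from weight-proportional dwell, a fixed lateral move time
between spots and an energy-layer switch time between layers, in
serpentine within-layer order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .beam import BeamFrame, BeamGeometry
from .density import HuDensityTable
from .grids import VoxelGrid
from .machine import MachineModel


@dataclass
class BeamField:
    """One treatment field: geometry plus vectorized spot data."""

    field_id: str
    gantry_angle_deg: float
    energies: np.ndarray  # (n_spots,) MeV
    u_mm: np.ndarray
    v_mm: np.ndarray
    weights: np.ndarray
    layers: np.ndarray  # (n_spots,) int layer index, 0 = most distal
    timestamps: Optional[np.ndarray] = None  # (n_spots,) s from field start

    @property
    def n_spots(self) -> int:
        return int(self.energies.size)

    def validate(self) -> None:
        if np.any(self.weights < 0):
            raise ValueError("spot weights must be non-negative")
        if self.timestamps is not None:
            if np.any(np.diff(self.timestamps) <= 0):
                raise ValueError("timestamps must be strictly increasing")


@dataclass
class Prescription:
    fraction_dose_gy_rbe: float = 1.8
    n_fractions: int = 28
    rbe: float = 1.1


@dataclass
class SpotPlan:
    """Two-field SFUD plan with prescription and normalization state."""

    fields: List[BeamField]
    prescription: Prescription = dc_field(default_factory=Prescription)

    def scaled(self, factor: float) -> "SpotPlan":
        new_fields = [
            BeamField(
                f.field_id,
                f.gantry_angle_deg,
                f.energies.copy(),
                f.u_mm.copy(),
                f.v_mm.copy(),
                f.weights * factor,
                f.layers.copy(),
                None if f.timestamps is None else f.timestamps.copy(),
            )
            for f in self.fields
        ]
        return SpotPlan(new_fields, self.prescription)

    def to_json(self, path) -> None:
        payload = {
            "prescription": {
                "fraction_dose_gy_rbe": self.prescription.fraction_dose_gy_rbe,
                "n_fractions": self.prescription.n_fractions,
                "rbe": self.prescription.rbe,
            },
            "fields": [
                {
                    "field_id": f.field_id,
                    "gantry_angle_deg": f.gantry_angle_deg,
                    "spots": [
                        {
                            "energy_mev": float(e),
                            "u_mm": float(u),
                            "v_mm": float(v),
                            "weight": float(w),
                            "layer": int(l),
                            "t_s": None if f.timestamps is None else float(t),
                        }
                        for e, u, v, w, l, t in zip(
                            f.energies,
                            f.u_mm,
                            f.v_mm,
                            f.weights,
                            f.layers,
                            f.timestamps
                            if f.timestamps is not None
                            else np.zeros(f.n_spots),
                        )
                    ],
                }
                for f in self.fields
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class PlanningOptions:
    spot_spacing_mm: float = 5.0
    layer_spacing_wepl_mm: float = 5.0
    target_dose_pct: float = 50.0  # per-field SFUD target (half prescription)
    lateral_margin_spots: int = 1
    distal_margin_mm: float = 2.0
    proximal_margin_mm: float = 2.0
    n_target_voxels: int = 3000
    max_iterations: int = 60
    residual_tol: float = 1e-4
    min_relative_weight: float = 1e-4


def _field_spot_grid(
    frame: BeamFrame,
    ptv_bev: np.ndarray,
    ptv_wepl: np.ndarray,
    machine: MachineModel,
    opts: PlanningOptions,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Lateral spot grid covering the PTV projection, per energy layer."""
    sp = opts.spot_spacing_mm
    m = opts.lateral_margin_spots * sp
    u0 = np.floor((ptv_bev[:, 0].min() - m) / sp) * sp
    u1 = np.ceil((ptv_bev[:, 0].max() + m) / sp) * sp
    v0 = np.floor((ptv_bev[:, 1].min() - m) / sp) * sp
    v1 = np.ceil((ptv_bev[:, 1].max() + m) / sp) * sp
    ug = np.arange(u0, u1 + 0.5 * sp, sp)
    vg = np.arange(v0, v1 + 0.5 * sp, sp)

    # keep lateral positions near the PTV projection (dilated by margin)
    occ = np.zeros((ug.size, vg.size), dtype=bool)
    iu = np.clip(np.round((ptv_bev[:, 0] - u0) / sp).astype(int), 0, ug.size - 1)
    iv = np.clip(np.round((ptv_bev[:, 1] - v0) / sp).astype(int), 0, vg.size - 1)
    occ[iu, iv] = True
    occ = ndimage.binary_dilation(occ, iterations=opts.lateral_margin_spots + 1)
    uu, vv = np.meshgrid(ug, vg, indexing="ij")
    lat_u = uu[occ]
    lat_v = vv[occ]

    w_lo = max(ptv_wepl.min() - opts.proximal_margin_mm, 1.0)
    w_hi = ptv_wepl.max() + opts.distal_margin_mm
    n_layers = max(int(np.ceil((w_hi - w_lo) / opts.layer_spacing_wepl_mm)) + 1, 1)
    layer_wepls = w_hi - opts.layer_spacing_wepl_mm * np.arange(n_layers)
    layer_wepls = layer_wepls[layer_wepls > 0.5]
    energies_per_layer = machine.energy_mev(layer_wepls)

    energies, us, vs, layers = [], [], [], []
    for li, e in enumerate(energies_per_layer):
        energies.append(np.full(lat_u.size, e))
        us.append(lat_u)
        vs.append(lat_v)
        layers.append(np.full(lat_u.size, li, dtype=int))
    return (
        np.concatenate(energies),
        np.concatenate(us),
        np.concatenate(vs),
        np.concatenate(layers),
    )


def _dose_matrix(
    vox_bev: np.ndarray,
    vox_wepl: np.ndarray,
    energies: np.ndarray,
    u_mm: np.ndarray,
    v_mm: np.ndarray,
    machine: MachineModel,
) -> np.ndarray:
    """Dose per unit weight of every spot at every target voxel."""
    n_vox = vox_bev.shape[0]
    n_spots = energies.size
    a = np.empty((n_vox, n_spots))
    sig = machine.sigma_mm(vox_wepl)
    norm = 1.0 / (2.0 * np.pi * sig**2)
    # group columns by energy so the depth dose is evaluated once per layer
    for e in np.unique(energies):
        cols = np.nonzero(energies == e)[0]
        depth = machine.bragg_depth_dose(float(e), vox_wepl)
        du = vox_bev[:, 0:1] - u_mm[cols][None, :]
        dv = vox_bev[:, 1:2] - v_mm[cols][None, :]
        lat = np.exp(-0.5 * (du**2 + dv**2) / sig[:, None] ** 2)
        a[:, cols] = (depth * norm)[:, None] * lat
    return a


def _optimize_weights(
    a: np.ndarray, target: np.ndarray, opts: PlanningOptions
) -> np.ndarray:
    """Non-negative uniform-dose weights by multiplicative updates.

    MLEM-style iteration w <- w * (A^T t) / (A^T A w); stops when the
    relative residual improvement drops below ``residual_tol`` or after
    ``max_iterations``.  The update is homogeneous of degree one in the
    target, so doubling the prescription exactly doubles the weights.
    """
    at_t = a.T @ target
    # near-uniform init with a gradient tilt: early-stopped multiplicative
    # updates keep the solution smooth, while the tilt resolves degenerate
    # problems (e.g. a single target voxel) toward the best-placed spot.
    # Scale-invariant in shape and linear in the target overall.
    w = 1.0 + at_t / max(at_t.max(), 1e-30)
    aw = a @ w
    w *= float(target @ aw) / max(float(aw @ aw), 1e-30)
    prev = np.inf
    for _ in range(opts.max_iterations):
        aw = a @ w
        denom = a.T @ aw
        w *= at_t / np.maximum(denom, 1e-30)
        resid = float(np.linalg.norm(a @ w - target) / np.linalg.norm(target))
        if prev - resid < opts.residual_tol * max(resid, 1e-30):
            break
        prev = resid
    return w


def plan_sfud(
    ct: VoxelGrid,
    structures,
    gantry_angles_deg: Sequence[float],
    machine: Optional[MachineModel] = None,
    table: Optional[HuDensityTable] = None,
    options: Optional[PlanningOptions] = None,
    prescription: Optional[Prescription] = None,
    seed: int = 0,
) -> SpotPlan:
    """Two-field SFUD plan on the static CT.

    Each field's spots cover the PTV on a regular lateral grid and on
    uniformly spaced WEPL layers; weights are optimized so each field
    alone delivers a uniform half of the prescription to the PTV.
    Raises if the PTV is outside the machine's reachable range.
    """
    machine = machine or MachineModel()
    table = table or HuDensityTable()
    opts = options or PlanningOptions()
    rng = np.random.default_rng(seed)

    ptv_idx = np.argwhere(structures["PTV"])
    pts = np.asarray(ct.origin) + ptv_idx * np.asarray(ct.spacing)

    fields: List[BeamField] = []
    for fi, angle in enumerate(gantry_angles_deg):
        geom = BeamGeometry(float(angle))
        ptv_bev = geom.to_bev(pts)
        frame = BeamFrame(
            ct,
            geom,
            u_range=(ptv_bev[:, 0].min() - 30.0, ptv_bev[:, 0].max() + 30.0),
            v_range=(ptv_bev[:, 1].min() - 30.0, ptv_bev[:, 1].max() + 30.0),
        )
        density = table(frame.sample_patient_values(ct.values))
        wepl = frame.wepl_from_density(density)

        idx = np.moveaxis(frame.bev_to_index(ptv_bev), -1, 0)
        ptv_wepl = ndimage.map_coordinates(wepl, idx, order=1, mode="nearest")

        max_range = float(machine.range_mm(machine.energy_max_mev))
        if ptv_wepl.max() + opts.distal_margin_mm > max_range:
            raise ValueError(
                f"PTV at WEPL {ptv_wepl.max():.0f} mm exceeds machine range "
                f"{max_range:.0f} mm"
            )

        energies, us, vs, layers = _field_spot_grid(
            frame, ptv_bev, ptv_wepl, machine, opts
        )

        n_t = min(opts.n_target_voxels, pts.shape[0])
        sel = rng.choice(pts.shape[0], size=n_t, replace=False)
        target = np.full(n_t, opts.target_dose_pct)  # in % units
        a = _dose_matrix(
            ptv_bev[sel], ptv_wepl[sel], energies, us, vs, machine
        )
        w = _optimize_weights(a, target, opts)

        keep = w > opts.min_relative_weight * w.max()
        fields.append(
            BeamField(
                field_id=f"F{fi}",
                gantry_angle_deg=float(angle),
                energies=energies[keep],
                u_mm=us[keep],
                v_mm=vs[keep],
                weights=w[keep],
                layers=layers[keep],
            )
        )
    return SpotPlan(fields, prescription or Prescription())


def delivery_timeline(plan: SpotPlan, machine: Optional[MachineModel] = None) -> SpotPlan:
    """Assign start timestamps to every spot of every field.

    Spots are ordered layer by layer (most distal first) and serpentine
    within a layer (rows of v, alternating u direction).  Time
    accumulates weight-proportional dwell, a lateral move between
    consecutive spots and an energy-layer switch between layers.  The
    dwell scale is ``machine.seconds_per_mu`` or, when unset,
    calibrated per field so the median dwell is the machine's target.
    """
    machine = machine or MachineModel()
    new_fields = []
    for f in plan.fields:
        order = _serpentine_order(f)
        e, u, v, w, lay = (
            f.energies[order],
            f.u_mm[order],
            f.v_mm[order],
            f.weights[order],
            f.layers[order],
        )
        if machine.seconds_per_mu is not None:
            spm = machine.seconds_per_mu
        else:
            med = float(np.median(w[w > 0])) if np.any(w > 0) else 1.0
            spm = machine.target_dwell_s / max(med, 1e-30)
        dwell = w * spm
        t = np.empty(w.size)
        clock = 0.0
        for i in range(w.size):
            if i > 0:
                clock += dwell[i - 1]
                if lay[i] != lay[i - 1]:
                    clock += machine.layer_switch_s
                else:
                    clock += machine.lateral_move_s
            t[i] = clock
        nf = BeamField(f.field_id, f.gantry_angle_deg, e, u, v, w, lay, t)
        nf.validate()
        new_fields.append(nf)
    return SpotPlan(new_fields, plan.prescription)


def _serpentine_order(f: BeamField) -> np.ndarray:
    """Delivery order: by layer, then v rows with alternating u sweep."""
    keys = []
    for i in range(f.n_spots):
        keys.append((f.layers[i], f.v_mm[i], f.u_mm[i]))
    order = sorted(
        range(f.n_spots),
        key=lambda i: (f.layers[i], f.v_mm[i], 0.0),
    )
    # regroup to apply alternating u within each (layer, v) row
    out: List[int] = []
    i = 0
    row_flip = False
    while i < len(order):
        j = i
        li, vi = f.layers[order[i]], f.v_mm[order[i]]
        while j < len(order) and f.layers[order[j]] == li and f.v_mm[order[j]] == vi:
            j += 1
        row = sorted(order[i:j], key=lambda k: f.u_mm[k], reverse=row_flip)
        out.extend(row)
        row_flip = not row_flip
        i = j
    return np.asarray(out, dtype=int)


def field_frame(
    ct: VoxelGrid,
    f: BeamField,
    geom: Optional[BeamGeometry] = None,
    margin_mm: float = 25.0,
) -> BeamFrame:
    """Beam frame restricted laterally to a field's spots plus margin.

    Dose beyond 3.5 lateral sigmas of every spot is zero, so a frame
    clipped a safe margin outside the spot envelope loses nothing.
    """
    if geom is None:
        geom = BeamGeometry(f.gantry_angle_deg)
    return BeamFrame(
        ct,
        geom,
        u_range=(f.u_mm.min() - margin_mm, f.u_mm.max() + margin_mm),
        v_range=(f.v_mm.min() - margin_mm, f.v_mm.max() + margin_mm),
    )


def compute_static_dose(
    plan: SpotPlan,
    ct: VoxelGrid,
    machine: Optional[MachineModel] = None,
    table: Optional[HuDensityTable] = None,
    method: str = "fft",
) -> VoxelGrid:
    """Superpose all fields' spots on the (static) CT: the 3D dose.

    Dose is computed in each field's beam frame and sampled back at the
    patient voxel centers; units follow the spot weights (use
    :func:`normalize_plan` to express doses in % of prescription).
    ``method`` selects the layer-wise Fourier synthesis (the default,
    shared with the 4D engine) or the direct per-spot superposition
    (``"spots"``, the reference path).
    """
    machine = machine or MachineModel()
    table = table or HuDensityTable()
    x, y, z = ct.meshgrid_mm()
    pts = np.stack([x, y, z], axis=-1)
    total = np.zeros(ct.shape)
    for f in plan.fields:
        geom = BeamGeometry(f.gantry_angle_deg)
        frame = field_frame(ct, f, geom)
        density = table(frame.sample_patient_values(ct.values))
        wepl = frame.wepl_from_density(density)
        deposit = (
            frame.deposit_layers_fft if method == "fft" else frame.deposit_spots
        )
        dose_beam = deposit(
            wepl, f.energies, f.u_mm, f.v_mm, f.weights, machine
        )
        idx = np.moveaxis(frame.bev_to_index(geom.to_bev(pts)), -1, 0)
        total += ndimage.map_coordinates(
            dose_beam, idx, order=1, mode="constant", cval=0.0
        )
    return ct.with_values(total)


def normalize_plan(
    plan: SpotPlan,
    ct: VoxelGrid,
    structures,
    machine: Optional[MachineModel] = None,
    table: Optional[HuDensityTable] = None,
) -> Tuple[SpotPlan, VoxelGrid]:
    """Scale spot weights so the static CTV median dose is 100%.

    Returns the normalized plan and its static dose in % of the
    prescription.  All 4D doses computed from the normalized plan are
    directly in % of the per-fraction prescription.
    """
    dose = compute_static_dose(plan, ct, machine, table)
    median = float(np.median(dose.values[structures["CTV"]]))
    if median <= 0:
        raise ValueError("CTV receives no dose; check plan geometry")
    factor = 100.0 / median
    return plan.scaled(factor), dose.with_values(dose.values * factor)
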