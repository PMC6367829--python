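"""Parameterized PBS machine model: beam physics and delivery dynamics.

The proton depth dose is an analytic Bragg curve tied to a power-law
range-energy relation R[cm] = alpha * E^p; the lateral profile is a
single Gaussian whose sigma grows linearly with radiological depth.
Delivery dynamics (spot dwell, lateral move time, energy-layer switch
time) are of the same order as scanned-proton gantries, so the spill
structure interacts with breathing periods of a few seconds.

This is a deliberately simplified, self-contained stand-in for a
clinical dose engine: the interplay statistics studied here depend on
the time structure and geometry of delivery, not on absolute dosimetric
fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass
class MachineModel:
    """Beam and delivery-dynamics parameters.

    Range-energy: R[cm] = alpha * E[MeV]^p (protons in water).
    Lateral spot size: sigma(wepl) = sigma0_mm + sigma_slope * wepl.
    Timing: dwell per spot is weight-proportional, calibrated so the
    median dwell equals ``target_dwell_s`` unless ``seconds_per_mu``
    is given explicitly.
    """

    alpha: float = 0.0022
    p: float = 1.77
    energy_min_mev: float = 30.0
    energy_max_mev: float = 250.0

    sigma0_mm: float = 3.0
    sigma_slope: float = 0.02

    # Bragg-curve shape: entrance plateau relative to peak, and the
    # relative weight of the straggling-broadened peak Gaussian.
    entrance_level: float = 0.30
    plateau_rise: float = 0.30
    straggling_floor_mm: float = 2.5

    lateral_move_s: float = 0.003
    layer_switch_s: float = 1.0
    target_dwell_s: float = 0.005
    seconds_per_mu: Optional[float] = None

    def range_mm(self, energy_mev) -> np.ndarray:
        """Proton range in water (mm) for energies in MeV."""
        e = np.asarray(energy_mev, dtype=float)
        return 10.0 * self.alpha * e**self.p

    def energy_mev(self, range_mm) -> np.ndarray:
        """Energy (MeV) whose range equals ``range_mm`` (inverse power law)."""
        r_cm = np.asarray(range_mm, dtype=float) / 10.0
        return (r_cm / self.alpha) ** (1.0 / self.p)

    def range_sigma_mm(self, range_mm: float) -> float:
        """Range-straggling width (mm), with a floor for shallow ranges."""
        r_cm = range_mm / 10.0
        return float(np.hypot(10.0 * 0.012 * r_cm**0.935, self.straggling_floor_mm))

    def sigma_mm(self, wepl_mm) -> np.ndarray:
        """Lateral Gaussian sigma (mm) at a given radiological depth."""
        return self.sigma0_mm + self.sigma_slope * np.asarray(wepl_mm, dtype=float)

    def bragg_depth_dose(self, energy_mev: float, wepl_mm) -> np.ndarray:
        """Relative depth dose at radiological depth(s), peak-normalized.

        A straggling-broadened Gaussian peak at R(E) rides on a gently
        rising entrance plateau that is switched off smoothly across
        the peak; dose is identically zero beyond the distal falloff
        (R + 4 sigma_R).
        """
        if not (self.energy_min_mev <= energy_mev <= self.energy_max_mev):
            raise ValueError(
                f"energy {energy_mev} MeV outside machine table "
                f"[{self.energy_min_mev}, {self.energy_max_mev}]"
            )
        z = np.asarray(wepl_mm, dtype=float)
        r = float(self.range_mm(energy_mev))
        dose = self._bragg_unnormalized(z, r) / self._peak_value(energy_mev, r)
        sig = self.range_sigma_mm(r)
        return np.where((z < 0) | (z > r + 4.0 * sig), 0.0, dose)

    def _bragg_unnormalized(self, z: np.ndarray, r: float) -> np.ndarray:
        sig = self.range_sigma_mm(r)
        peak = np.exp(-0.5 * ((z - r) / sig) ** 2)
        # plateau: entrance_level at z=0 rising by plateau_rise toward the
        # peak, faded out by a logistic across the peak region
        rise = 1.0 + self.plateau_rise * np.clip(z / r, 0.0, 1.0)
        fade = 1.0 / (1.0 + np.exp((z - r) / sig))
        return peak + self.entrance_level * rise * fade

    def _peak_value(self, energy_mev: float, r: float) -> float:
        """Maximum of the unnormalized curve, cached per energy."""
        cache = getattr(self, "_peak_cache", None)
        if cache is None:
            cache = self._peak_cache = {}
        key = round(float(energy_mev), 9)
        if key not in cache:
            sig = self.range_sigma_mm(r)
            zfine = np.linspace(max(r - 6 * sig, 0.0), r + 2 * sig, 2001)
            cache[key] = float(self._bragg_unnormalized(zfine, r).max())
        return cache[key]
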