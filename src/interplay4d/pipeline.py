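"""Desk-scale study orchestration: phantom -> plan -> QA -> 4D -> statistics.

`run_study` executes, for every configured pseudo-patient, the full
chain the per-module APIs expose — synthetic phantom, breathing
measurements, ITV/PTV derivation, SFUD planning, deformation-field QA,
the single-fraction (4Dx1) interplay ensemble, stochastic 28-fraction
treatments (4Dx28), the single- vs multi-measurement longitudinal
comparison — and joins everything into summary tables plus the
four-row weighted correlation analysis across patients.

All randomness derives from one study seed; rerunning with the same
configuration writes byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .correlation import PatientObservation, correlation_suite
from .four_d import InterplayEngine, enumerate_single_fraction
from .fractionation import (
    first_n_to_coverage,
    fractionation_curve,
    longitudinal_comparison,
    simulate_ensemble,
)
from .machine import MachineModel
from .metrics import compare_scenarios, structure_metrics
from .motion import (
    Amplitudes,
    MotionInput,
    derive_itv_ptv,
    generate_motion_input,
    rescale_period,
)
from .motion_analysis import ctv_motion_distribution, day_to_day_variation
from .phantom import PhantomConfig, build_phantom
from .planning import PlanningOptions, delivery_timeline, normalize_plan, plan_sfud
from .qa import qa_report
from .scenario import PatientScenario

log = logging.getLogger("interplay4d")


@dataclass
class MeasurementConfig:
    """One measured-analog breathing pattern of a pseudo-patient."""

    is_mm: float
    ap_mm: float
    lr_mm: float
    period_s: float


@dataclass
class PatientConfig:
    patient_id: str
    ctv_volume_cc: float
    measurements: List[MeasurementConfig]
    rescaled_periods: List[float] = field(default_factory=list)
    gantry_angles: Tuple[float, float] = (160.0, 210.0)


@dataclass
class StudyConfig:
    patients: List[PatientConfig]
    shape: Tuple[int, int, int] = (48, 48, 48)
    spacing: Tuple[float, float, float] = (4.0, 4.0, 4.0)
    n_fractions: int = 28
    n_sim: int = 5
    n_sim_longitudinal: int = 10
    starting_phase_mode: str = "diagonal"
    seed: int = 20260927

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        patients = [
            PatientConfig(
                patient_id=p["patient_id"],
                ctv_volume_cc=p["ctv_volume_cc"],
                measurements=[MeasurementConfig(**m) for m in p["measurements"]],
                rescaled_periods=list(p.get("rescaled_periods", [])),
                gantry_angles=tuple(p.get("gantry_angles", (160.0, 210.0))),
            )
            for p in d["patients"]
        ]
        kwargs = {k: v for k, v in d.items() if k != "patients"}
        if "shape" in kwargs:
            kwargs["shape"] = tuple(kwargs["shape"])
        if "spacing" in kwargs:
            kwargs["spacing"] = tuple(kwargs["spacing"])
        return cls(patients=patients, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_study_config() -> StudyConfig:
    """Nine pseudo-patients spanning the studied motion regime.

    CTV motion amplitudes span 2-15 mm IS (the cohort regime "< 15 mm")
    with AP/LR components of a few mm; breathing periods lie in
    [2.8, 10] s and trend longer for larger amplitudes, emulating the
    reported positive period-amplitude association.  Patients differ in
    CTV volume (33-195 cc) and in the number of repeated measurements
    (1-3, the correlation weights); period-rescaled variants of the
    first measurement emulate artificially varied breathing cycles.
    """
    spec = [
        # id, ctv cc, [(is, ap, lr, T), ...], rescaled periods, angles
        ("P1", 51.9, [(8.0, 3.0, 2.0, 7.1), (6.5, 2.5, 1.5, 3.8)], [3.0], (160, 210)),
        ("P2", 33.0, [(5.0, 2.0, 1.0, 3.8), (6.0, 2.5, 1.5, 2.8), (5.5, 2.0, 1.0, 3.7)], [], (160, 210)),
        ("P3", 95.1, [(12.0, 3.5, 2.5, 9.7), (10.5, 3.0, 2.0, 8.2), (11.0, 3.0, 2.5, 8.8)], [], (160, 210)),
        ("P4", 87.8, [(7.0, 2.5, 2.0, 3.7)], [5.5], (20, 340)),
        ("P5", 194.8, [(4.0, 1.5, 1.0, 3.7)], [8.0], (20, 340)),
        ("P6", 115.1, [(2.0, 1.0, 0.5, 5.6)], [3.0], (20, 340)),
        ("P7", 112.0, [(10.0, 3.0, 2.0, 10.0)], [5.0], (160, 200)),
        ("P8", 62.4, [(15.0, 4.0, 3.0, 4.7), (13.5, 3.5, 2.5, 5.6)], [10.0], (20, 340)),
        ("P9", 46.0, [(3.0, 1.5, 1.0, 3.7), (3.5, 1.5, 1.0, 2.9)], [], (20, 340)),
    ]
    patients = [
        PatientConfig(
            patient_id=pid,
            ctv_volume_cc=vol,
            measurements=[
                MeasurementConfig(is_mm=a, ap_mm=b, lr_mm=c, period_s=t)
                for a, b, c, t in meas
            ],
            rescaled_periods=resc,
            gantry_angles=angles,
        )
        for pid, vol, meas, resc, angles in spec
    ]
    return StudyConfig(patients=patients)


def build_patient_scenario(
    pconf: PatientConfig, study: StudyConfig, seed: int
) -> PatientScenario:
    """Phantom + motion inputs for one pseudo-patient."""
    phantom_cfg = PhantomConfig(
        shape=tuple(study.shape),
        spacing=tuple(study.spacing),
        ctv_volume_cc=pconf.ctv_volume_cc,
    )
    ct, structures = build_phantom(phantom_cfg)
    focus = structures.centroid_mm("CTV")
    seeds = np.random.SeedSequence(seed).generate_state(len(pconf.measurements))
    motions: List[MotionInput] = []
    for mi, mc in enumerate(pconf.measurements):
        motions.append(
            generate_motion_input(
                ct,
                Amplitudes(is_mm=mc.is_mm, ap_mm=mc.ap_mm, lr_mm=mc.lr_mm),
                mc.period_s,
                focus,
                motion_id=f"m{mi + 1}",
                seed=int(seeds[mi] % (2**31)),
            )
        )
    for T in pconf.rescaled_periods:
        motions.append(rescale_period(motions[0], T))
    itv, ptv = derive_itv_ptv(structures["CTV"], motions, ct.spacing, ct.origin)
    structures["ITV"] = itv
    structures["PTV"] = ptv
    structures.validate()
    return PatientScenario(
        patient_id=pconf.patient_id,
        ct=ct,
        structures=structures,
        motions=motions,
        gantry_angles_deg=tuple(pconf.gantry_angles),
    )


def run_patient(
    pconf: PatientConfig,
    study: StudyConfig,
    seed: int,
    machine: Optional[MachineModel] = None,
) -> Dict[str, object]:
    """All per-patient stages; returns a dict of result tables/scalars."""
    t0 = time.time()
    machine = machine or MachineModel()
    scenario = build_patient_scenario(pconf, study, seed)
    ct, ss = scenario.ct, scenario.structures

    plan = plan_sfud(ct, ss, scenario.gantry_angles_deg, machine=machine, seed=seed)
    plan, static = normalize_plan(plan, ct, ss, machine=machine)
    plan = delivery_timeline(plan, machine)
    static_ctv = structure_metrics(static.values, ss["CTV"])
    log.info("%s: plan ready (%.1f s)", pconf.patient_id, time.time() - t0)

    qa = qa_report(ct, ss, scenario.motions)

    summaries = [
        ctv_motion_distribution(m, ss["CTV"]) for m in scenario.motions
    ]
    motion_frame = pd.concat([s.to_frame() for s in summaries], ignore_index=True)
    motion_frame.insert(0, "patient", pconf.patient_id)
    d2d = (
        day_to_day_variation(summaries) if len(summaries) > 1 else None
    )

    engine = InterplayEngine(plan, ct, ss, scenario.motions, machine=machine)
    ens = enumerate_single_fraction(engine, mode=study.starting_phase_mode)
    log.info("%s: 4Dx1 ensemble done (%.1f s)", pconf.patient_id, time.time() - t0)

    sims = simulate_ensemble(
        engine, study.n_sim, study.n_fractions, seed=seed + 1
    )
    curve = fractionation_curve(sims)
    coverage = pd.DataFrame([first_n_to_coverage(r) for r in sims])
    d5d95_28 = np.array([r.metric_at("d5d95", study.n_fractions) for r in sims])

    longi = None
    if len(scenario.motions) >= 2:
        longi = longitudinal_comparison(
            engine,
            single_m=scenario.motions[0].motion_id,
            n_sim=study.n_sim_longitudinal,
            n_fractions=study.n_fractions,
            seed=seed + 2,
        )

    amplitude = float(np.mean([s.magnitude_mean for s in summaries]))
    obs = PatientObservation(
        patient_id=pconf.patient_id,
        amplitude_mm=amplitude,
        period_s=float(np.mean([m.period_s for m in scenario.motions])),
        d5d95=float(ens["d5d95"].mean()),
        ctv_volume_cc=ss.volume_cc("CTV"),
        weight=scenario.n_measurements,
    )

    summary = {
        "patient": pconf.patient_id,
        "ctv_cc": round(ss.volume_cc("CTV"), 2),
        "amplitude_mm": round(amplitude, 3),
        "mean_period_s": obs.period_s,
        "n_measurements": scenario.n_measurements,
        "n_motion_inputs": len(scenario.motions),
        "static_d5d95": static_ctv["d5d95"],
        "static_v95": static_ctv["v95"],
        "static_v107": static_ctv["v107"],
        "static_d2": static_ctv["d2"],
        "static_dmean": static_ctv["dmean"],
        "x1_d5d95_mean": float(ens["d5d95"].mean()),
        "x1_d5d95_max": float(ens["d5d95"].max()),
        "x1_v95_mean": float(ens["v95"].mean()),
        "x1_v95_min": float(ens["v95"].min()),
        "x28_d5d95_mean": float(d5d95_28.mean()),
        "x28_d5d95_median": float(np.median(d5d95_28)),
        "first_n_v95_100_mean": float(coverage["first_n_v95_100"].mean()),
        "qa_mean_jacobian": qa.mean_jacobian,
        "qa_mean_mass_ratio": qa.mean_mass_ratio,
    }
    log.info("%s: done (%.1f s)", pconf.patient_id, time.time() - t0)
    return {
        "summary": summary,
        "observation": obs,
        "qa": qa.rows.assign(patient=pconf.patient_id),
        "motion": motion_frame,
        "day_to_day": d2d,
        "ensemble": ens.assign(patient=pconf.patient_id),
        "curve": curve.assign(patient=pconf.patient_id),
        "longitudinal": None
        if longi is None
        else longi.assign(patient=pconf.patient_id),
    }


def run_study(
    config: StudyConfig,
    out_dir,
    machine: Optional[MachineModel] = None,
    resume: bool = True,
) -> Dict[str, pd.DataFrame]:
    """Run all pseudo-patients and write the study tables to ``out_dir``.

    Tables: summary.csv (per-patient static/4Dx1/4Dx28 join),
    correlations.csv (the four-row weighted analysis), qa.csv,
    motion.csv, ensemble.csv, fractionation.csv, longitudinal.csv.
    The resolved configuration is written next to the outputs; with
    ``resume``, per-patient results cached under the configuration hash
    are reused.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.resolved.yaml")
    cache_dir = out / "cache" / config.config_hash()
    cache_dir.mkdir(parents=True, exist_ok=True)

    seeds = np.random.SeedSequence(config.seed).generate_state(len(config.patients))
    results = []
    for pconf, seed in zip(config.patients, seeds):
        cache_file = cache_dir / f"{pconf.patient_id}.pkl"
        if resume and cache_file.exists():
            res = pd.read_pickle(cache_file)
            log.info("%s: reusing cached stage output", pconf.patient_id)
        else:
            res = run_patient(pconf, config, int(seed % (2**31)), machine)
            pd.to_pickle(res, cache_file)
        results.append(res)

    frames: Dict[str, pd.DataFrame] = {}
    frames["summary"] = pd.DataFrame([r["summary"] for r in results])
    obs = [r["observation"] for r in results]
    if len(obs) >= 3:
        frames["correlations"] = correlation_suite(obs)
    frames["qa"] = pd.concat([r["qa"] for r in results], ignore_index=True)
    d2d = [
        r["day_to_day"].assign(patient=r["summary"]["patient"])
        for r in results
        if r["day_to_day"] is not None
    ]
    if d2d:
        frames["day_to_day"] = pd.concat(d2d, ignore_index=True)
    frames["motion"] = pd.concat([r["motion"] for r in results], ignore_index=True)
    frames["ensemble"] = pd.concat([r["ensemble"] for r in results], ignore_index=True)
    frames["fractionation"] = pd.concat(
        [r["curve"] for r in results], ignore_index=True
    )
    longi = [r["longitudinal"] for r in results if r["longitudinal"] is not None]
    if longi:
        frames["longitudinal"] = pd.concat(longi, ignore_index=True)

    for name, frame in frames.items():
        frame.to_csv(out / f"{name}.csv", index=False, float_format="%.8g")
    return frames
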