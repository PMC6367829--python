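"""Shared fixtures: phantoms, motion inputs, plans and 4D engines.

The heavier session fixtures build one desk-scale scenario each and are
shared across test modules; everything is generated programmatically.
"""

from __future__ import annotations

import numpy as np
import pytest

from interplay4d.four_d import InterplayEngine
from interplay4d.machine import MachineModel
from interplay4d.motion import (
    Amplitudes,
    derive_itv_ptv,
    generate_motion_input,
    rescale_period,
)
from interplay4d.phantom import PhantomConfig, build_phantom
from interplay4d.planning import delivery_timeline, normalize_plan, plan_sfud


@pytest.fixture(scope="session")
def phantom48():
    """Default phantom on a 48^3 grid at 4 mm (fast unit-test scale)."""
    cfg = PhantomConfig(shape=(48, 48, 48), spacing=(4.0, 4.0, 4.0))
    ct, structures = build_phantom(cfg)
    return ct, structures


@pytest.fixture(scope="session")
def phantom64():
    """Default phantom on a 64^3 grid at 3 mm (study scale)."""
    cfg = PhantomConfig(shape=(64, 64, 64), spacing=(3.0, 3.0, 3.0))
    ct, structures = build_phantom(cfg)
    return ct, structures


@pytest.fixture(scope="session")
def motion8(phantom64):
    """The default breathing measurement: 8/3/2 mm (IS/AP/LR), T=5.5 s."""
    ct, ss = phantom64
    return generate_motion_input(
        ct, Amplitudes(8.0, 3.0, 2.0), 5.5, ss.centroid_mm("CTV"), motion_id="m8"
    )


@pytest.fixture(scope="session")
def study64(phantom64, motion8):
    """Planned 64^3 scenario with the full motion library and 4D engine.

    Motion inputs: the default 8 mm measurement with period-rescaled
    variants at T=3 and 10 s; a second, larger measurement (12 mm,
    T=3.8 s) emulating day-to-day variation; and a 5-point IS-amplitude
    sweep (2-15 mm) at fixed T=4 s with everything else held fixed.
    The ITV/PTV and the SFUD plan derive from the default measurement
    only, so the sweep probes motion against one fixed plan.
    """
    ct, ss = phantom64
    focus = ss.centroid_mm("CTV")
    machine = MachineModel()

    m8 = motion8
    motions = [m8, rescale_period(m8, 3.0), rescale_period(m8, 10.0)]
    motions.append(
        generate_motion_input(
            ct, Amplitudes(12.0, 3.5, 2.5), 3.8, focus, motion_id="m12"
        )
    )
    sweep_ids = []
    for a in (2.0, 5.0, 8.0, 11.0, 15.0):
        mid = f"a{a:g}"
        sweep_ids.append(mid)
        motions.append(
            generate_motion_input(
                ct, Amplitudes(a, 3.0, 2.0), 4.0, focus, motion_id=mid
            )
        )

    itv, ptv = derive_itv_ptv(ss["CTV"], m8, ct.spacing, ct.origin)
    ss["ITV"] = itv
    ss["PTV"] = ptv
    ss.validate()

    plan = plan_sfud(ct, ss, (160.0, 210.0), machine=machine, seed=7)
    plan, static = normalize_plan(plan, ct, ss, machine=machine)
    plan = delivery_timeline(plan, machine)
    engine = InterplayEngine(plan, ct, ss, motions, machine=machine)
    return {
        "ct": ct,
        "structures": ss,
        "machine": machine,
        "plan": plan,
        "static": static,
        "engine": engine,
        "sweep_ids": sweep_ids,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
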