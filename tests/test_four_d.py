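"""4D dose accumulation: phase assignment, limits and ensembles."""

import numpy as np
import pytest
from scipy import ndimage

from interplay4d.four_d import (
    InterplayEngine,
    StartingPhasePair,
    assign_spots_to_phases,
    enumerate_single_fraction,
)
from interplay4d.machine import MachineModel
from interplay4d.metrics import metrics_from_values
from interplay4d.motion import (
    Amplitudes,
    MotionInput,
    generate_motion_input,
    phase_image,
    sin2_temporal_factors,
)
from interplay4d.planning import (
    BeamField,
    SpotPlan,
    compute_static_dose,
    delivery_timeline,
    normalize_plan,
    plan_sfud,
)


class TestPhaseAssignment:
    def test_bin_width_example(self):
        # T = 4 s -> bin width 0.2 s; t = 0.3 s falls in bin 1
        assert assign_spots_to_phases(np.array([0.3]), 4.0, 0)[0] == 1

    def test_t_zero_gives_start_phase(self):
        for start in (0, 7, 19):
            assert assign_spots_to_phases(np.array([0.0]), 7.3, start)[0] == start

    def test_full_period_wraps(self):
        assert assign_spots_to_phases(np.array([4.0]), 4.0, 0)[0] == 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            assign_spots_to_phases(np.array([0.0]), -1.0, 0)
        with pytest.raises(ValueError):
            StartingPhasePair(0, 21)


@pytest.fixture(scope="module")
def zero_motion_engine(phantom48):
    ct, ss = phantom48
    machine = MachineModel()
    m0 = generate_motion_input(
        ct, Amplitudes(0, 0, 0), 4.0, ss.centroid_mm("CTV"), motion_id="m0"
    )
    plan = plan_sfud(ct, ss, (160.0, 210.0), machine=machine, seed=1)
    plan, _ = normalize_plan(plan, ct, ss, machine=machine)
    plan = delivery_timeline(plan, machine)
    return InterplayEngine(plan, ct, ss, [m0], machine=machine)


class TestStaticLimit:
    def test_zero_motion_fraction_equals_static(self, zero_motion_engine):
        eng = zero_motion_engine
        static = eng.static_dose().values
        fd = eng.compute_4d_dose("m0", StartingPhasePair(3, 11), full=True)
        assert np.max(np.abs(fd.dose.values - static)) < 1e-3
        assert np.max(np.abs(fd.ctv_dose - eng.static_ctv_dose())) < 1e-3

    def test_zero_motion_ensemble_members_identical(self, zero_motion_engine):
        df = enumerate_single_fraction(zero_motion_engine, mode="diagonal")
        assert len(df) == 20
        assert df["d5d95"].std() < 1e-9
        assert df["dmean"].std() < 1e-9


class TestSinglePhaseOracle:
    def test_all_spots_in_one_phase_matches_two_step_oracle(self, phantom48):
        """Freezing delivery in phase j must equal: static dose on the
        phase CT, pulled back by sampling at x + u_j(x)."""
        ct, ss = phantom48
        machine = MachineModel()
        motion = generate_motion_input(
            ct, Amplitudes(8, 3, 2), 4.0, ss.centroid_mm("CTV"), motion_id="m1"
        )
        plan = plan_sfud(ct, ss, (160.0, 210.0), machine=machine, seed=1)
        plan, _ = normalize_plan(plan, ct, ss, machine=machine)
        plan = delivery_timeline(plan, machine)
        # force every spot into the starting phase: all timestamps zero
        frozen_fields = [
            BeamField(f.field_id, f.gantry_angle_deg, f.energies, f.u_mm,
                      f.v_mm, f.weights, f.layers,
                      np.arange(f.n_spots) * 1e-9)
            for f in plan.fields
        ]
        frozen = SpotPlan(frozen_fields, plan.prescription)
        eng = InterplayEngine(frozen, ct, ss, [motion], machine=machine)
        j = 10
        got = eng.compute_4d_dose("m1", StartingPhasePair(j, j), full=True)

        ct_j = phase_image(ct, motion, j)
        dose_j = compute_static_dose(frozen, ct_j, machine)
        dvf = motion.field(j)
        idx = np.indices(ct.shape, dtype=float)
        coords = idx + np.moveaxis(dvf.displacement, -1, 0) / np.asarray(
            ct.spacing
        )[:, None, None, None]
        oracle = ndimage.map_coordinates(
            dose_j.values, coords, order=1, mode="constant", cval=0.0
        )
        # same physics through two interpolation routes: the oracle
        # resamples twice (phase CT on the patient grid, then the beam
        # frame), so agreement is limited by grid smoothing
        diff = np.abs(got.dose.values - oracle)
        assert np.max(diff) < 0.08 * oracle.max()
        high = oracle > 0.5 * oracle.max()
        assert np.mean(diff[high]) < 0.02 * oracle.max()


class TestEnsemble:
    def test_sizes_match_configuration(self, study64):
        eng = study64["engine"]
        assert len(enumerate_single_fraction(eng, ["m8"], mode="diagonal")) == 20
        assert len(enumerate_single_fraction(eng, ["m8"], mode="grid")) == 400
        with pytest.raises(ValueError):
            enumerate_single_fraction(eng, ["m8"], mode="bogus")

    def test_nonzero_motion_spreads_metrics(self, study64):
        df = enumerate_single_fraction(study64["engine"], ["m8"], mode="diagonal")
        assert df["d5d95"].max() - df["d5d95"].min() > 0.0
        assert df["d5d95"].min() > 1.0

    def test_start_phase_average_equals_phase_average(self, study64):
        """Uniform average over starting phases is exactly the
        phase-averaged dose (linearity of the delivery groups)."""
        eng = study64["engine"]
        avg_starts = np.mean(
            [eng.field_dose_4d("m8", 0, i) for i in range(20)], axis=0
        )
        # oracle: full field delivered entirely in each phase, then averaged
        f = eng.plan.fields[0]
        frozen = SpotPlan(
            [BeamField(f.field_id, f.gantry_angle_deg, f.energies, f.u_mm,
                       f.v_mm, f.weights, f.layers,
                       np.arange(f.n_spots) * 1e-9)],
            eng.plan.prescription,
        )
        eng2 = InterplayEngine(
            frozen, study64["ct"], study64["structures"],
            [m for m in eng.motions.values() if m.motion_id == "m8"],
            machine=eng.machine,
        )
        phase_avg = np.mean(
            [eng2.field_dose_4d("m8", 0, j) for j in range(20)], axis=0
        )
        assert np.allclose(avg_starts, phase_avg, rtol=0, atol=2e-2)

    def test_ensemble_mean_dmean_close_to_static(self, study64):
        """4Dx1 ensemble-mean CTV dmean stays within 1% of static."""
        eng = study64["engine"]
        df = enumerate_single_fraction(eng, ["m8"], mode="diagonal")
        static_dmean = metrics_from_values(eng.static_ctv_dose())["dmean"]
        assert df["dmean"].mean() == pytest.approx(static_dmean, rel=0.01)


class TestRigidConservation:
    def test_rigid_motion_conserves_integral_dose(self, phantom48):
        """Rigid fully-in-grid motion in a homogeneous medium keeps the
        integrated fraction dose within 1% of static."""
        ct, ss = phantom48
        water = ct.with_values(np.zeros(ct.shape))
        machine = MachineModel()
        plan = plan_sfud(water, ss, (160.0, 210.0), machine=machine, seed=1)
        plan, _ = normalize_plan(plan, water, ss, machine=machine)
        plan = delivery_timeline(plan, machine)
        rigid = MotionInput(
            motion_id="rigid",
            period_s=4.0,
            envelope=np.ones(ct.shape, dtype=np.float32),
            temporal=sin2_temporal_factors(),
            direction_mm=np.array([0.0, 0.0, -8.0]),
            spacing=ct.spacing,
            origin=ct.origin,
        )
        eng = InterplayEngine(plan, water, ss, [rigid], machine=machine)
        static_sum = eng.static_dose().values.sum()
        fd = eng.compute_4d_dose("rigid", StartingPhasePair(5, 12), full=True)
        assert fd.dose.values.sum() == pytest.approx(static_sum, rel=0.01)
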