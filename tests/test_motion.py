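"""Breathing-field generation, warping and motion-derived target volumes."""

import numpy as np
import pytest

from interplay4d.grids import DeformationField, VoxelGrid
from interplay4d.motion import (
    Amplitudes,
    MotionInput,
    derive_itv_ptv,
    generate_motion_input,
    phase_image,
    rescale_period,
    sin2_temporal_factors,
    warp_image,
    warp_mask_forward,
)


@pytest.fixture(scope="module")
def grid32():
    n, sp = 32, 6.0
    origin = tuple(-0.5 * (n - 1) * sp for _ in range(3))
    return VoxelGrid(np.zeros((n, n, n)), (sp, sp, sp), origin)


@pytest.fixture(scope="module")
def motion32(grid32):
    return generate_motion_input(
        grid32, Amplitudes(8.0, 3.0, 2.0), 4.0, (0.0, 0.0, 0.0), motion_id="m1"
    )


class TestGeneration:
    def test_focus_amplitude_matches_request(self, motion32, grid32):
        ein = motion32.ein_phase
        disp = motion32.field(ein).displacement
        center = tuple(s // 2 for s in grid32.shape)
        # focus lies mid-grid; requested (LR, AP, IS) = (2, 3, 8) magnitudes
        at_focus = np.abs(disp[center])
        assert at_focus == pytest.approx([2.0, 3.0, 8.0], rel=0.05)

    def test_phase0_is_zero_and_ein_is_10(self, motion32):
        assert motion32.field(0).is_zero()
        assert motion32.ein_phase == 10

    def test_sin2_temporal_factor_at_phase5(self, motion32):
        # sin^2(pi*5/20) = 1/2 of the EIN amplitude, evaluated at the focus
        d5 = np.abs(motion32.field(5).displacement).max()
        d10 = np.abs(motion32.field(10).displacement).max()
        assert d5 == pytest.approx(0.5 * d10, rel=0.02)

    def test_zero_amplitudes_give_zero_fields(self, grid32):
        m = generate_motion_input(
            grid32, Amplitudes(0, 0, 0), 4.0, (0.0, 0.0, 0.0)
        )
        assert all(m.field(j).is_zero() for j in range(20))

    def test_seed_reproducibility(self, grid32):
        args = (grid32, Amplitudes(8, 3, 2), 4.0, (0.0, 0.0, 0.0))
        a = generate_motion_input(*args, seed=11)
        b = generate_motion_input(*args, seed=11)
        c = generate_motion_input(*args, seed=12)
        assert np.array_equal(a.envelope, b.envelope)
        assert not np.array_equal(a.envelope, c.envelope)

    def test_folding_amplitude_rejected(self, grid32):
        with pytest.raises(ValueError, match="fold"):
            generate_motion_input(
                grid32, Amplitudes(400.0, 0.0, 0.0), 4.0, (0.0, 0.0, 0.0)
            )

    def test_period_outside_range_rejected(self, grid32):
        with pytest.raises(ValueError, match="period"):
            generate_motion_input(
                grid32, Amplitudes(5, 2, 1), 2.0, (0.0, 0.0, 0.0)
            )

    def test_amplitude_resolution_consistency(self):
        """Halving the spacing changes the focus amplitude by < 2%."""
        amps = []
        for n, sp in ((32, 6.0), (64, 3.0)):
            origin = tuple(-0.5 * (n - 1) * sp for _ in range(3))
            g = VoxelGrid(np.zeros((n, n, n)), (sp, sp, sp), origin)
            m = generate_motion_input(g, Amplitudes(8, 3, 2), 4.0, (0, 0, 0))
            amps.append(np.abs(m.field(10).displacement).max())
        assert amps[0] == pytest.approx(amps[1], rel=0.02)


class TestRescalePeriod:
    def test_fields_shared_only_period_changes(self, motion32):
        r = rescale_period(motion32, 3.0)
        assert r.period_s == 3.0
        assert r.source_id == "m1"
        assert not r.measured
        assert np.array_equal(
            r.field(10).displacement, motion32.field(10).displacement
        )

    def test_rescale_to_same_period_is_identity_on_fields(self, motion32):
        r = rescale_period(motion32, motion32.period_s)
        assert r.period_s == motion32.period_s
        assert np.array_equal(r.envelope, motion32.envelope)

    def test_rescale_composition(self, motion32):
        twice = rescale_period(rescale_period(motion32, 3.0), 10.0)
        once = rescale_period(motion32, 10.0)
        assert twice.period_s == once.period_s == 10.0
        assert np.array_equal(twice.envelope, once.envelope)
        assert twice.source_id == once.source_id == "m1"


def _trilinear_oracle(values, pt):
    """Hand-rolled trilinear interpolation at one fractional index."""
    i0 = np.floor(pt).astype(int)
    f = pt - i0
    out = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (f[0] if dx else 1 - f[0])
                    * (f[1] if dy else 1 - f[1])
                    * (f[2] if dz else 1 - f[2])
                )
                out += w * values[i0[0] + dx, i0[1] + dy, i0[2] + dz]
    return out


class TestWarping:
    def test_zero_field_identity(self, grid32):
        img = grid32.with_values(np.random.default_rng(0).normal(size=grid32.shape))
        dvf = DeformationField(np.zeros(grid32.shape + (3,)), grid32.spacing,
                               grid32.origin)
        assert np.array_equal(warp_image(img, dvf).values, img.values)

    def test_one_voxel_translation_moves_edge(self, grid32):
        vals = np.zeros(grid32.shape)
        vals[:, :, 16:] = 100.0  # step edge along IS
        img = grid32.with_values(vals)
        disp = np.zeros(grid32.shape + (3,))
        disp[..., 2] = grid32.spacing[2]  # sample one voxel superior
        warped = warp_image(img, DeformationField(disp, grid32.spacing,
                                                  grid32.origin))
        assert np.array_equal(warped.values[:, :, 15:-1], vals[:, :, 16:])

    def test_smooth_field_matches_pointwise_oracle(self, grid32, rng):
        x, y, z = grid32.meshgrid_mm()
        img = grid32.with_values(np.sin(x / 40.0) + np.cos(y / 30.0) * z / 90.0)
        disp = np.stack(
            [3.0 * np.sin(y / 50.0), 2.0 * np.cos(z / 60.0), 4.0 * np.sin(x / 70.0)],
            axis=-1,
        )
        dvf = DeformationField(disp, grid32.spacing, grid32.origin)
        warped = warp_image(img, dvf, fill_value=0.0)
        idx = np.indices(grid32.shape, dtype=float)
        for _ in range(25):
            v = tuple(rng.integers(4, 28, size=3))
            pt = np.array(
                [idx[c][v] + disp[v][c] / grid32.spacing[c] for c in range(3)]
            )
            assert warped.values[v] == pytest.approx(
                _trilinear_oracle(img.values, pt), abs=1e-6
            )

    def test_grid_mismatch_rejected(self, grid32):
        img = grid32.with_values(np.zeros(grid32.shape))
        dvf = DeformationField(np.zeros((8, 8, 8, 3)), grid32.spacing)
        with pytest.raises(ValueError, match="different grids"):
            warp_image(img, dvf)

    def test_phase_image_moves_anatomy_with_material(self, grid32, motion32):
        """A bright blob at the focus moves along +u in the phase CT."""
        vals = np.full(grid32.shape, -1000.0)
        c = grid32.shape[0] // 2
        vals[c - 2 : c + 3, c - 2 : c + 3, c - 2 : c + 3] = 500.0
        img = grid32.with_values(vals)
        ph = phase_image(img, motion32, motion32.ein_phase, fill_value=-1000.0)
        com_ref = np.array(
            [(img.values > 0).nonzero()[a].mean() for a in range(3)]
        )
        com_ph = np.array([(ph.values > 0).nonzero()[a].mean() for a in range(3)])
        shift_mm = (com_ph - com_ref) * np.asarray(grid32.spacing)
        # material displacement at the focus is (+2, +3, -8) mm
        assert shift_mm == pytest.approx([2.0, 3.0, -8.0], abs=2.5)


class TestItvPtv:
    def test_zero_motion_itv_equals_ctv(self, grid32):
        ctv = np.zeros(grid32.shape, dtype=bool)
        ctv[12:20, 12:20, 12:20] = True
        m = generate_motion_input(grid32, Amplitudes(0, 0, 0), 4.0, (0, 0, 0))
        itv, ptv = derive_itv_ptv(ctv, m, grid32.spacing, grid32.origin)
        assert np.array_equal(itv, ctv)

    def test_zero_margin_ptv_equals_itv(self, grid32, motion32):
        ctv = np.zeros(grid32.shape, dtype=bool)
        ctv[12:20, 12:20, 12:20] = True
        itv, ptv = derive_itv_ptv(
            ctv, motion32, grid32.spacing, grid32.origin, margin_mm=0.0
        )
        assert np.array_equal(ptv, itv)

    def test_rigid_translation_extends_is_extent(self, grid32):
        """Minkowski-sum oracle: rigid 12 mm IS peak motion adds 12 mm."""
        ctv = np.zeros(grid32.shape, dtype=bool)
        ctv[12:20, 12:20, 12:20] = True
        disp_peak = 12.0
        env = np.ones(grid32.shape, dtype=np.float32)
        m = MotionInput(
            motion_id="rigid",
            period_s=4.0,
            envelope=env,
            temporal=sin2_temporal_factors(),
            direction_mm=np.array([0.0, 0.0, -disp_peak]),
            spacing=grid32.spacing,
            origin=grid32.origin,
        )
        itv, _ = derive_itv_ptv(ctv, m, grid32.spacing, grid32.origin)
        extent_ctv = np.ptp(np.nonzero(ctv.any(axis=(0, 1)))[0])
        extent_itv = np.ptp(np.nonzero(itv.any(axis=(0, 1)))[0])
        added_mm = (extent_itv - extent_ctv) * grid32.spacing[2]
        assert added_mm == pytest.approx(disp_peak, abs=grid32.spacing[2])

    def test_itv_contains_pushed_ctv_per_phase(self, grid32, motion32):
        ctv = np.zeros(grid32.shape, dtype=bool)
        ctv[12:20, 12:20, 12:20] = True
        itv, ptv = derive_itv_ptv(ctv, motion32, grid32.spacing, grid32.origin)
        for j in (5, 10, 15):
            pushed = warp_mask_forward(ctv, motion32.field(j))
            assert not np.any(pushed & ~itv)
        assert not np.any(itv & ~ptv)
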