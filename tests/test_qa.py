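"""Jacobian-determinant and mass-conservation QA of deformation fields."""

import numpy as np
import pytest

from interplay4d.density import HuDensityTable
from interplay4d.grids import DeformationField, VoxelGrid
from interplay4d.motion import Amplitudes, generate_motion_input
from interplay4d.qa import jacobian_determinant_map, mass_conservation_ratio, qa_report


def _grid(n=24, sp=5.0):
    origin = tuple(-0.5 * (n - 1) * sp for _ in range(3))
    return VoxelGrid(np.zeros((n, n, n)), (sp, sp, sp), origin)


def _zero_dvf(grid):
    return DeformationField(np.zeros(grid.shape + (3,)), grid.spacing, grid.origin)


class TestJacobian:
    def test_identity_field_is_one_everywhere(self):
        det = jacobian_determinant_map(_zero_dvf(_grid()))
        assert np.allclose(det.values, 1.0, atol=1e-14)

    def test_linear_expansion_is_analytic(self):
        grid = _grid()
        x, _, _ = grid.meshgrid_mm()
        disp = np.zeros(grid.shape + (3,))
        disp[..., 0] = 0.1 * x
        det = jacobian_determinant_map(
            DeformationField(disp, grid.spacing, grid.origin)
        )
        assert np.allclose(det.values, 1.1, atol=1e-9)

    def test_matches_fourth_order_stencil_oracle(self, rng):
        """Independent oracle: 4th-order central differences."""
        grid = _grid(n=30, sp=4.0)
        x, y, z = grid.meshgrid_mm()
        disp = np.stack(
            [
                2.0 * np.sin(x / 40) * np.cos(y / 50),
                1.5 * np.cos(z / 45) * np.sin(x / 55),
                3.0 * np.sin(y / 35),
            ],
            axis=-1,
        )
        dvf = DeformationField(disp, grid.spacing, grid.origin)
        det = jacobian_determinant_map(dvf).values

        def d4(arr, axis, h):
            out = np.zeros_like(arr)
            s = [slice(None)] * 3
            for shift, coef in ((-2, 1), (-1, -8), (1, 8), (2, -1)):
                out += coef * np.roll(arr, -shift, axis=axis)
            return out / (12 * h)

        jac = np.zeros(grid.shape + (3, 3))
        for c in range(3):
            for a in range(3):
                jac[..., c, a] = d4(disp[..., c], a, grid.spacing[a])
            jac[..., c, c] += 1.0
        oracle = np.linalg.det(jac)
        interior = (slice(3, -3),) * 3
        assert np.max(np.abs(det[interior] - oracle[interior])) < 1e-3

    def test_composition_of_small_fields(self):
        """det J of composed fields equals the product at first order."""
        grid = _grid()
        x, y, _ = grid.meshgrid_mm()
        d1 = np.zeros(grid.shape + (3,))
        d1[..., 0] = 0.02 * x
        d2 = np.zeros(grid.shape + (3,))
        d2[..., 1] = 0.03 * y
        composed = DeformationField(d1 + d2, grid.spacing, grid.origin)
        det1 = jacobian_determinant_map(
            DeformationField(d1, grid.spacing, grid.origin)
        ).values
        det2 = jacobian_determinant_map(
            DeformationField(d2, grid.spacing, grid.origin)
        ).values
        det12 = jacobian_determinant_map(composed).values
        assert np.max(np.abs(det12 - det1 * det2)) < 1e-2

    def test_folding_detected(self):
        grid = _grid()
        x, _, _ = grid.meshgrid_mm()
        disp = np.zeros(grid.shape + (3,))
        disp[..., 0] = -1.5 * x  # reflection: det = -0.5
        det = jacobian_determinant_map(
            DeformationField(disp, grid.spacing, grid.origin)
        )
        assert int((det.values <= 0).sum()) > 0


class TestMassRatio:
    def _uniform_ct(self, grid, hu=0.0):
        return grid.with_values(np.full(grid.shape, hu))

    def _center_mask(self, grid, half=5):
        mask = np.zeros(grid.shape, dtype=bool)
        c = grid.shape[0] // 2
        mask[c - half : c + half, c - half : c + half, c - half : c + half] = True
        return mask

    def test_identity_is_exactly_one(self):
        grid = _grid()
        ct = self._uniform_ct(grid, hu=60.0)
        ratio = mass_conservation_ratio(
            ct, _zero_dvf(grid), self._center_mask(grid)
        )
        assert ratio == 1.0

    def test_uniform_expansion_scales_mass(self):
        """det J ~ 1.1 expansion on uniform density: ratio ~ 1/1.1.

        Analytic oracle: the pushed delineation occupies det J times the
        EEX volume while the density stays uniform, so the mass ratio is
        1/det J.  A spherical mask on a fine grid keeps the
        nearest-neighbour warp's voxelization error small.
        """
        grid = _grid(n=80, sp=2.0)
        ct = self._uniform_ct(grid, hu=0.0)
        x, y, z = grid.meshgrid_mm()
        c = 1.1 ** (1.0 / 3.0) - 1.0  # isotropic, det J = 1.1
        disp = np.stack([c * x, c * y, c * z], axis=-1)
        dvf = DeformationField(disp, grid.spacing, grid.origin)
        ball = x**2 + y**2 + z**2 <= 50.0**2
        ratio = mass_conservation_ratio(ct, dvf, ball)
        assert ratio == pytest.approx(1.0 / 1.1, rel=0.02)

    def test_translation_conserves_mass(self):
        grid = _grid(n=32, sp=4.0)
        ct = self._uniform_ct(grid, hu=50.0)
        disp = np.zeros(grid.shape + (3,))
        disp[..., 2] = 8.0
        dvf = DeformationField(disp, grid.spacing, grid.origin)
        ratio = mass_conservation_ratio(ct, dvf, self._center_mask(grid, half=4))
        assert ratio == pytest.approx(1.0, rel=0.01)

    def test_mask_order_invariance_and_empty_mask(self):
        grid = _grid()
        ct = self._uniform_ct(grid, hu=30.0)
        with pytest.raises(ValueError, match="empty"):
            mass_conservation_ratio(ct, _zero_dvf(grid), np.zeros(grid.shape, bool))


class TestQaReport:
    def test_zero_motion_report_is_trivial(self, phantom48):
        ct, ss = phantom48
        m = generate_motion_input(
            ct, Amplitudes(0, 0, 0), 4.0, ss.centroid_mm("CTV")
        )
        report = qa_report(ct, ss, m)
        assert np.allclose(report.rows["mean_jacobian"], 1.0)
        assert np.allclose(report.rows["mass_ratio"], 1.0)
        assert not report.has_folding

    def test_default_motion_is_near_volume_conserving(self, phantom48):
        """Mean Jacobian inside OARs stays within 10% of unity."""
        ct, ss = phantom48
        m = generate_motion_input(
            ct, Amplitudes(8, 3, 2), 4.0, ss.centroid_mm("CTV")
        )
        report = qa_report(ct, ss, m)
        assert np.all(np.abs(report.rows["mean_jacobian"] - 1.0) < 0.1)
        assert not report.has_folding
        assert report.rows["mass_ratio"].between(0.8, 1.25).all()

    def test_report_serializes_to_csv(self, phantom48, tmp_path):
        ct, ss = phantom48
        m = generate_motion_input(
            ct, Amplitudes(5, 2, 1), 4.0, ss.centroid_mm("CTV")
        )
        report = qa_report(ct, ss, m)
        out = tmp_path / "qa.csv"
        report.to_csv(out)
        text = out.read_text()
        assert "mass_ratio" in text and "liver" in text
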