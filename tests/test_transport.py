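"""Transport kernel: validation, conservation, determinism, oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from drdifc.transport import (
    FluenceGrid,
    GeometryError,
    OpticalMedium,
    OptodeSpec,
    TimeGates,
    TimeGatedFluence,
    cw_integrate,
    diffusion_green,
    run_photon_mc,
    run_photon_mc_gated,
)


@pytest.fixture()
def small_medium():
    return OpticalMedium(extent=(20.0, 20.0, 10.0), voxel=0.5)


class TestValidation:
    def test_zero_photons_rejected(self, small_medium):
        src = OptodeSpec((0.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="n_photons"):
            run_photon_mc(small_medium, src, 0, seed=1)

    def test_optode_off_surface_rejected(self):
        with pytest.raises(GeometryError, match="surface"):
            OptodeSpec((0.0, 0.0, 1.0))

    def test_optode_outside_lateral_extent_rejected(self, small_medium):
        src = OptodeSpec((50.0, 0.0, 0.0))
        with pytest.raises(GeometryError, match="lateral"):
            run_photon_mc(small_medium, src, 100, seed=1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mu_a": -0.1},
            {"mu_s": 0.0},
            {"g": 1.5},
            {"voxel": 0.3},  # 20 mm not an integer multiple of 0.3
            {"n_in": 0.5},
        ],
    )
    def test_medium_invariants(self, kwargs):
        params = {"extent": (20.0, 20.0, 10.0), "voxel": 0.5, **kwargs}
        with pytest.raises(ValueError):
            OpticalMedium(**params)


class TestConservation:
    def test_nonabsorbing_weight_tally_closes_exactly(self):
        """With mu_a = 0 no weight is absorbed or rouletted, so launched
        weight must equal escaped weight exactly."""
        med = OpticalMedium(
            mu_a=0.0, extent=(20.0, 20.0, 10.0), voxel=0.5
        )
        src = OptodeSpec((0.0, 0.0, 0.0))
        gated, tally = run_photon_mc_gated(med, src, 20_000, seed=3)
        assert tally.absorbed == 0.0
        assert tally.roulette_killed == 0.0
        assert tally.accounted == pytest.approx(tally.launched, rel=1e-12)
        assert np.all(gated.values == 0.0)

    def test_absorbing_tally_closes_within_roulette_tolerance(
        self, small_medium
    ):
        src = OptodeSpec((0.0, 0.0, 0.0))
        _, tally = run_photon_mc_gated(small_medium, src, 50_000, seed=4)
        # roulette preserves weight only in expectation
        assert tally.accounted == pytest.approx(tally.launched, rel=1e-3)
        assert tally.absorbed <= tally.launched


class TestDeterminismAndPositivity:
    def test_fixed_seed_bit_identical(self, small_medium):
        src = OptodeSpec((1.0, 0.0, 0.0))
        a = run_photon_mc(small_medium, src, 50_000, seed=42)
        b = run_photon_mc(small_medium, src, 50_000, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_different_seeds_differ(self, small_medium):
        src = OptodeSpec((1.0, 0.0, 0.0))
        a = run_photon_mc(small_medium, src, 50_000, seed=42)
        b = run_photon_mc(small_medium, src, 50_000, seed=43)
        assert not np.array_equal(a.values, b.values)

    def test_fluence_nonnegative_finite(self, small_medium):
        det = OptodeSpec((0.0, 0.0, 0.0), role="detector", beam="cone", na=0.5)
        grid = run_photon_mc(small_medium, det, 50_000, seed=5)
        assert np.all(grid.values >= 0)
        assert np.all(np.isfinite(grid.values))


class TestCwIntegrate:
    def _gated(self, medium, values, gates):
        src = OptodeSpec((0.0, 0.0, 0.0))
        return TimeGatedFluence(values, gates, medium, src, 1, 0)

    def test_zero_input_gives_zero_output(self):
        med = OpticalMedium(extent=(5.0, 5.0, 5.0), voxel=1.0)
        gates = TimeGates(4, 8.0)
        gated = self._gated(med, np.zeros((4, 5, 5, 5)), gates)
        assert np.all(cw_integrate(gated).values == 0.0)

    def test_single_gate_constant_scales_by_width(self):
        med = OpticalMedium(extent=(5.0, 5.0, 5.0), voxel=1.0)
        gates = TimeGates(1, 2.5)
        gated = self._gated(med, np.full((1, 5, 5, 5), 3.0), gates)
        assert np.allclose(cw_integrate(gated).values, 3.0 * 2.5)

    def test_matches_per_voxel_loop_oracle(self, rng):
        med = OpticalMedium(extent=(5.0, 5.0, 5.0), voxel=1.0)
        gates = TimeGates(3, 6.0)
        values = rng.random((3, 5, 5, 5))
        cw = cw_integrate(self._gated(med, values, gates)).values
        # independent brute-force loop
        expected = np.zeros((5, 5, 5))
        for gi in range(3):
            for i in range(5):
                for j in range(5):
                    for k in range(5):
                        expected[i, j, k] += values[gi, i, j, k] * (6.0 / 3)
        assert np.allclose(cw, expected, rtol=1e-14)

    def test_gate_mismatch_rejected(self):
        med = OpticalMedium(extent=(5.0, 5.0, 5.0), voxel=1.0)
        gated = self._gated(med, np.zeros((3, 5, 5, 5)), TimeGates(3, 6.0))
        with pytest.raises(ValueError, match="gate"):
            cw_integrate(gated, TimeGates(4, 6.0))


def _two_image_source_reference(mu_a, mu_sp, n_rel, rho, z):
    """Independent evaluation of the extrapolated-boundary point-source
    formula, written out from scratch for cross-checking."""
    d = 1.0 / (3.0 * (mu_a + mu_sp))
    mu_eff = math.sqrt(3.0 * mu_a * (mu_a + mu_sp))
    z0 = 1.0 / (mu_a + mu_sp)
    r_eff = -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    zb = 2.0 * d * (1.0 + r_eff) / (1.0 - r_eff)
    r1 = math.hypot(rho, z - z0)
    r2 = math.hypot(rho, z + z0 + 2 * zb)
    return (
        math.exp(-mu_eff * r1) / r1 - math.exp(-mu_eff * r2) / r2
    ) / (4.0 * math.pi * d)


class TestDiffusionGreen:
    def setup_method(self):
        self.med = OpticalMedium(extent=(30.0, 30.0, 30.0), voxel=0.5)

    def test_decays_with_distance(self):
        vals = [
            diffusion_green(self.med, (0, 0, 0), (r, 0.0, 1.0))
            for r in (1.0, 3.0, 6.0, 10.0, 14.0)
        ]
        assert all(a > b > 0 for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 0.01 * vals[0]

    def test_axial_mirror_symmetry(self):
        a = diffusion_green(self.med, (0, 0, 0), (2.5, 1.0, 1.5))
        b = diffusion_green(self.med, (0, 0, 0), (-2.5, -1.0, 1.5))
        assert a == pytest.approx(b, rel=1e-14)

    def test_matches_independent_reference_value(self):
        got = diffusion_green(self.med, (0, 0, 0), (5.0, 0.0, 1.0))
        want = _two_image_source_reference(
            mu_a=0.002, mu_sp=0.7, n_rel=1.37, rho=5.0, z=1.0
        )
        assert got == pytest.approx(want, rel=1e-12)

    def test_outside_position_rejected(self):
        with pytest.raises(GeometryError):
            diffusion_green(self.med, (0, 0, 0), (0.0, 0.0, 50.0))


class TestMonteCarloVersusDiffusion:
    def test_discrepancy_shrinks_from_near_field_to_diffusive_window(
        self, mc_fluence_10m
    ):
        """Within ~1 transport mean free path of the beam, diffusion theory
        is a poor description and the MC disagrees most; by ~3 mm the two
        should be much closer.  (Beyond ~4 mm the finite absorbing box
        truncates the MC, so the comparison window stops there.)"""
        med, grid = mc_fluence_10m

        def log_discrepancy(rho):
            mc = grid.at((rho, 0.0, 0.5))
            th = diffusion_green(med, (0.0, 0.0, 0.0), (rho, 0.0, 0.5))
            return abs(math.log(mc / th))

        assert log_discrepancy(1.0) > 2.0 * log_discrepancy(3.0)


class TestMonteCarloStatistics:
    def test_standard_error_scales_as_inverse_sqrt_n(self):
        """Across-seed standard error over a fixed voxel shell should drop
        by ~1/sqrt(2) when the photon budget doubles."""
        med = OpticalMedium(extent=(10.0, 10.0, 5.0), voxel=0.5)
        src = OptodeSpec((0.0, 0.0, 0.0))
        # fixed shell: voxels 2-3 mm from the entry point
        x = med.axis_centers(0)[:, None, None]
        y = med.axis_centers(1)[None, :, None]
        z = med.axis_centers(2)[None, None, :]
        r = np.sqrt(x**2 + y**2 + z**2)
        shell = (r > 2.0) & (r < 3.0)

        def shell_std(n, seeds):
            vals = np.array(
                [
                    run_photon_mc(med, src, n, seed=s).values[shell]
                    for s in seeds
                ]
            )
            return np.mean(np.std(vals, axis=0, ddof=1))

        s1 = shell_std(40_000, range(20, 28))
        s2 = shell_std(80_000, range(60, 68))
        assert s1 / s2 == pytest.approx(math.sqrt(2.0), rel=0.20)
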