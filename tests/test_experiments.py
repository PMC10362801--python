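"""SNR maps, flow traces, depth scans and pNC sweeps on analytic grids.

Most tests run on synthetic sensitivity grids with closed-form spatial
structure so expected values can be computed by independent loops; the
Monte-Carlo-dependent signatures are covered by the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from drdifc.experiments import (
    PairGrids,
    _deepest_unity_crossing,
    baseline_state,
    build_pair_grids,
    depth_scan,
    flow_trace,
    pnc_sweep,
    snr_map,
)
from drdifc.fluorescence import AFModel, SensitivityGrid, TargetModel
from drdifc.measurements import (
    MeasurementGeometry,
    default_geometry,
    dual_ratio,
    validate_dr_layout,
)
from drdifc.noise import NoiseParams
from drdifc.transport import (
    GeometryError,
    OpticalMedium,
    OptodeSpec,
    run_photon_mc,
)

P_SRC = 75.0
NOISE = NoiseParams(sigma_rel=0.031, p_nc=0.05)
AF = AFModel(kind="homogeneous", coefficient=5e-8)


@pytest.fixture(scope="module")
def toy_pairs() -> PairGrids:
    """Analytic four-pair grids: laterally Gaussian, exponentially decaying
    in depth, slightly different amplitude per slot."""
    geom = default_geometry()
    med = OpticalMedium(extent=(8.0, 8.0, 8.0), voxel=0.5)
    x = med.axis_centers(0)[:, None, None]
    y = med.axis_centers(1)[None, :, None]
    z = med.axis_centers(2)[None, None, :]
    _, assignment, _ = validate_dr_layout(geom)
    slots = {}
    amps = {"s_I": 1.0, "l_I": 0.7, "s_II": 0.95, "l_II": 0.72}
    for slot, pair in assignment.items():
        det, src = pair[0], pair[1:]
        xc = 0.5 * (
            geom.detectors[det].position[0] + geom.sources[src].position[0]
        )
        w = (
            amps[slot]
            * np.exp(-((x - xc) ** 2 + y**2) / 8.0)
            * np.exp(-z / 1.5)
        )
        slots[slot] = SensitivityGrid(w, med, (src, det))
    return PairGrids(slots, geom, assignment)


class TestSnrMap:
    def test_zero_target_coefficient_gives_zero_map(self, toy_pairs):
        for dt in ("sd:s_I", "dr"):
            m = snr_map(
                toy_pairs, AF, 0.0, NOISE, P_SRC, dt, noise_method="delta"
            )
            assert np.all(m.values == 0.0)

    def test_sd_map_matches_brute_force_position_loop(self, toy_pairs):
        """Independent recomputation: for each position, total reflectance
        with the target there minus baseline, over sigma_rel * R0."""
        m = snr_map(
            toy_pairs, AF, 4e-5, NOISE, P_SRC, "sd:s_I", noise_method="delta"
        )
        med = toy_pairs.medium
        w = toy_pairs.slots["s_I"]
        z_centers = med.axis_centers(2)
        r0 = P_SRC * float(
            np.sum(w.values * AF.profile(z_centers)[None, None, :])
        )
        iy = med.shape[1] // 2
        for ix in range(0, med.shape[0], 3):
            for iz in range(0, med.shape[2], 3):
                r_with = r0 + P_SRC * w.values[ix, iy, iz] * 4e-5
                expected = (r_with - r0) / (NOISE.sigma_rel * r0)
                assert m.values[ix, iz] == pytest.approx(expected, rel=1e-12)

    def test_dr_map_matches_scalar_dual_ratio_recomputation(self, toy_pairs):
        m = snr_map(
            toy_pairs, AF, 4e-5, NOISE, P_SRC, "dr", noise_method="delta"
        )
        med = toy_pairs.medium
        base = baseline_state(toy_pairs, AF, NOISE, P_SRC, "delta")
        iy = med.shape[1] // 2
        order = ("s_I", "l_I", "s_II", "l_II")
        for ix, iz in [(3, 2), (8, 5), (12, 9)]:
            quartet = [
                base.r0[s]
                + P_SRC * toy_pairs.slots[s].values[ix, iy, iz] * 4e-5
                for s in order
            ]
            expected = (dual_ratio(np.array(quartet)) - base.dr0) / (
                base.dr_sigma
            )
            assert m.values[ix, iz] == pytest.approx(expected, rel=1e-10)

    def test_sampling_noise_close_to_delta_method(self, toy_pairs):
        m_samp = snr_map(
            toy_pairs, AF, 4e-5, NOISE, P_SRC, "dr",
            noise_method="sampling", n_draws=200_000, seed=3,
        )
        m_delta = snr_map(
            toy_pairs, AF, 4e-5, NOISE, P_SRC, "dr", noise_method="delta"
        )
        ratio = m_samp.values[10, 4] / m_delta.values[10, 4]
        assert ratio == pytest.approx(1.0, abs=0.05)


class TestFlowTrace:
    def _path(self, med, depth, axis="x"):
        c = med.axis_centers(0)
        if axis == "x":
            return np.column_stack(
                [c, np.zeros_like(c), np.full_like(c, depth)]
            )
        return np.column_stack(
            [np.zeros_like(c), c, np.full_like(c, depth)]
        )

    def test_velocity_scales_time_axis_only(self, toy_pairs):
        pos = self._path(toy_pairs.medium, 1.25)
        t1, v1 = flow_trace(
            toy_pairs, AF, TargetModel(coefficient=4e-5, velocity=25.0),
            NOISE, P_SRC, "sd:s_I", pos, noise_method="delta",
        )
        t2, v2 = flow_trace(
            toy_pairs, AF, TargetModel(coefficient=4e-5, velocity=50.0),
            NOISE, P_SRC, "sd:s_I", pos, noise_method="delta",
        )
        assert np.allclose(v1, v2)
        assert np.allclose(t1, 2.0 * t2)

    def test_matches_snr_map_along_path(self, toy_pairs):
        """Map/trace consistency: same voxels, same values."""
        med = toy_pairs.medium
        pos = self._path(med, 1.25)
        _, vals = flow_trace(
            toy_pairs, AF, TargetModel(coefficient=4e-5), NOISE, P_SRC,
            "dr", pos, noise_method="delta",
        )
        m = snr_map(toy_pairs, AF, 4e-5, NOISE, P_SRC, "dr",
                    noise_method="delta")
        iz = int(1.25 / med.voxel)
        assert np.allclose(vals, m.values[:, iz], rtol=1e-12)

    def test_perpendicular_path_supported(self, toy_pairs):
        pos = self._path(toy_pairs.medium, 1.25, axis="y")
        _, vals = flow_trace(
            toy_pairs, AF, TargetModel(coefficient=4e-5), NOISE, P_SRC,
            "sd:s_I", pos, noise_method="delta",
        )
        assert np.all(np.isfinite(vals))
        assert vals.max() > 0

    def test_path_outside_medium_rejected(self, toy_pairs):
        pos = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 100.0]])
        with pytest.raises(GeometryError, match="path"):
            flow_trace(
                toy_pairs, AF, TargetModel(coefficient=4e-5), NOISE, P_SRC,
                "sd:s_I", pos,
            )


class TestDepthScan:
    def test_interpolated_crossing_matches_closed_form(self):
        """A synthetic exponential SNR profile crosses |SNR|=1 at a depth
        known in closed form; the scan's linear interpolation must land
        within half a voxel of it."""
        z = np.arange(0.25, 8.0, 0.5)
        s0, L = 40.0, 1.1
        prof = s0 * np.exp(-z / L)
        exact = L * np.log(s0)
        got = _deepest_unity_crossing(z, prof)
        assert got == pytest.approx(exact, abs=0.25)

    def test_no_crossing_returns_none(self):
        z = np.arange(0.25, 8.0, 0.5)
        assert _deepest_unity_crossing(z, np.full_like(z, 0.5)) is None

    def test_zero_target_reports_no_depth(self, toy_pairs):
        scan = depth_scan(
            toy_pairs, AF, 0.0, NOISE, P_SRC, ("sd:s_I", "dr"),
            noise_method="delta",
        )
        assert scan.max_depth["sd:s_I"] is None
        assert scan.max_depth["dr"] is None

    def test_centroids_follow_optode_positions(self, toy_pairs):
        scan = depth_scan(
            toy_pairs, AF, 4e-5, NOISE, P_SRC, ("sd:s_I", "sd:l_I", "dr"),
            noise_method="delta",
        )
        assert scan.centroid_x["sd:s_I"] == pytest.approx(-2.0)  # pair A1
        assert scan.centroid_x["sd:l_I"] == pytest.approx(-1.5)  # pair A2
        assert scan.centroid_x["dr"] == pytest.approx(0.0)


class TestPncSweep:
    def test_sd_depth_constant_dr_depth_monotone(self, toy_pairs):
        grid = [0.02, 0.05, 0.1, 0.2, 0.5, 1.0]
        sweep = pnc_sweep(
            toy_pairs, AF, 4e-5, 0.031, P_SRC, grid,
            ("sd:s_I", "dr"), noise_method="delta",
        )
        sd = sweep.max_depth["sd:s_I"]
        assert len(set(sd)) == 1
        dr = sweep.max_depth["dr"]
        assert all(a >= b for a, b in zip(dr, dr[1:]))

    def test_invalid_pnc_rejected(self, toy_pairs):
        with pytest.raises(ValueError):
            pnc_sweep(toy_pairs, AF, 4e-5, 0.031, P_SRC, [0.5, 1.2])


class TestBuildPairGrids:
    def test_asymmetric_layout_rejected(self):
        geom = MeasurementGeometry(
            sources={
                "1": OptodeSpec((-0.5, 0.0, 0.0), role="source"),
                "2": OptodeSpec((0.5, 0.0, 0.0), role="source"),
            },
            detectors={
                "A": OptodeSpec((-3.5, 0.0, 0.0), role="detector", beam="cone"),
                "B": OptodeSpec((3.0, 0.0, 0.0), role="detector", beam="cone"),
            },
        )
        with pytest.raises(GeometryError, match="layout"):
            build_pair_grids({}, geom)


class TestBeamModelAsymmetry:
    def test_swapping_beam_models_flips_doublet_asymmetry(self):
        """With a pencil source and cone detector the sensitivity under the
        source exceeds that under the detector at shallow depth; swapping
        the beam models reverses the inequality."""
        med = OpticalMedium(extent=(16.0, 16.0, 8.0), voxel=0.25)
        n = 1_500_000
        pencil_src = run_photon_mc(
            med, OptodeSpec((-0.5, 0, 0), role="source", beam="pencil"),
            n, seed=71,
        )
        cone_det = run_photon_mc(
            med,
            OptodeSpec((-3.5, 0, 0), role="detector", beam="cone", na=0.5),
            n, seed=72,
        )
        cone_src = run_photon_mc(
            med,
            OptodeSpec((-0.5, 0, 0), role="detector", beam="cone", na=0.5),
            n, seed=73,
        )
        pencil_det = run_photon_mc(
            med, OptodeSpec((-3.5, 0, 0), role="source", beam="pencil"),
            n, seed=74,
        )
        z = 1.25
        under_src = (-0.5, 0.0, z)
        under_det = (-3.5, 0.0, z)

        def w_at(phi_a, phi_b, pos):
            return phi_a.at(pos) * phi_b.at(pos)

        normal = w_at(pencil_src, cone_det, under_src) / w_at(
            pencil_src, cone_det, under_det
        )
        swapped = w_at(cone_src, pencil_det, under_src) / w_at(
            cone_src, pencil_det, under_det
        )
        assert normal > 1.0
        assert swapped < 1.0
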