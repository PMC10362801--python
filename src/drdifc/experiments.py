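"""Headline analyses: SNR maps, flow traces, depth scans and pNC sweeps.

Each analysis asks the same question in a different geometry: if a point
fluorescent target sits at position r, how many baseline noise standard
deviations does it move a given measurement type?  The measurement types
are the four single-distance (SD) pairs and the dual ratio (DR) built from
them.  Baseline (target-absent) intensities come from the distributed AF
background; SD baseline noise is σrel·R0 analytically, DR baseline noise is
estimated by sampling the coupling-coefficient model (the reference) or by
the delta-method closed form sqrt(pNC)·σrel·DR0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fluorescence import AFModel, SensitivityGrid, background_reflectance, sensitivity_map
from .measurements import (
    PAIR_ORDER,
    MeasurementGeometry,
    default_geometry,
    dual_ratio,
    validate_dr_layout,
)
from .noise import NoiseParams, dr_noise_delta_method, dr_noise_stats, snr
from .transport import FluenceGrid, GeometryError, OpticalMedium

__all__ = [
    "PairGrids",
    "SNRMap",
    "DepthScanResult",
    "build_pair_grids",
    "baseline_state",
    "snr_map",
    "flow_trace",
    "depth_scan",
    "pnc_sweep",
]


@dataclass
class PairGrids:
    """Sensitivity grids for the four DR pairs, keyed by quartet slot.

    ``assignment`` maps each slot (s_I, l_I, s_II, l_II) to the pair name
    (e.g. "A1") it came from, as validated by the DR layout check.
    """

    slots: dict[str, SensitivityGrid]
    geometry: MeasurementGeometry
    assignment: dict[str, str]

    @property
    def medium(self) -> OpticalMedium:
        return next(iter(self.slots.values())).medium

    def centroid_x(self, data_type: str) -> float:
        """Mean surface x of the optodes participating in a data type."""
        if data_type == "dr":
            xs = [o.position[0] for o in self.geometry.sources.values()]
            xs += [o.position[0] for o in self.geometry.detectors.values()]
        else:
            slot = _slot_of(data_type)
            pair = self.assignment[slot]
            det, src = pair[0], pair[1:]
            xs = [
                self.geometry.detectors[det].position[0],
                self.geometry.sources[src].position[0],
            ]
        return float(np.mean(xs))


def _slot_of(data_type: str) -> str:
    if not data_type.startswith("sd:") or data_type[3:] not in PAIR_ORDER:
        raise ValueError(
            f"data_type must be 'dr' or 'sd:<slot>' with slot in "
            f"{PAIR_ORDER}, got {data_type!r}"
        )
    return data_type[3:]


def build_pair_grids(
    fluences: dict[str, FluenceGrid], geometry: MeasurementGeometry | None = None
) -> PairGrids:
    """Assemble the four-pair Jacobians from per-optode fluence maps.

    ``fluences`` is keyed by optode name (sources "1", "2"; detectors "A",
    "B").  The DR layout is validated first; an asymmetric layout raises.
    """
    if geometry is None:
        geometry = default_geometry()
    valid, assignment, diag = validate_dr_layout(geometry)
    if not valid:
        raise GeometryError(f"invalid DR layout: {diag}")
    slots = {}
    for slot, pair in assignment.items():
        det, src = pair[0], pair[1:]
        slots[slot] = sensitivity_map(fluences[src], fluences[det])
    return PairGrids(slots, geometry, assignment)


@dataclass
class BaselineState:
    """Target-absent reflectances and noise levels, computed once."""

    r0: dict[str, float]  # per slot, mW mm^-2
    dr0: float
    sd_sigma: dict[str, float]
    dr_sigma: float


def baseline_state(
    pairs: PairGrids,
    af: AFModel,
    noise_params: NoiseParams,
    p_src: float,
    noise_method: str = "sampling",
    n_draws: int = 10_000,
    seed: int = 0,
) -> BaselineState:
    """Baseline intensities and noise for all data types."""
    r0 = {
        slot: background_reflectance(w, af, p_src)
        for slot, w in pairs.slots.items()
    }
    quartet = np.array([r0[s] for s in PAIR_ORDER])
    dr0 = dual_ratio(quartet)
    sd_sigma = {s: noise_params.sigma_rel * r0[s] for s in PAIR_ORDER}
    if noise_method == "delta":
        dr_sigma = dr_noise_delta_method(quartet, noise_params)
    elif noise_method == "sampling":
        _, dr_sigma = dr_noise_stats(quartet, noise_params, n_draws, seed)
        if dr_sigma == 0.0:  # pNC = 0: exact cancellation, no DR noise
            dr_sigma = dr_noise_delta_method(quartet, noise_params)
    else:
        raise ValueError(f"unknown noise_method {noise_method!r}")
    return BaselineState(r0, dr0, sd_sigma, dr_sigma)


def _w_planes(pairs: PairGrids) -> dict[str, np.ndarray]:
    """W on the y=0 voxel plane, per slot, shape (nx, nz)."""
    med = pairs.medium
    iy = med.shape[1] // 2
    return {s: w.values[:, iy, :] for s, w in pairs.slots.items()}


def _snr_from_w(
    w_arrays: dict[str, np.ndarray],
    base: BaselineState,
    target_coeff: float,
    p_src: float,
    data_type: str,
) -> np.ndarray:
    """Signed SNR for target positions given W values there (vectorized)."""
    if data_type == "dr":
        if base.dr_sigma <= 0:
            raise ValueError("undefined SNR: DR baseline noise is zero")
        rel = {
            s: 1.0 + p_src * w_arrays[s] * target_coeff / base.r0[s]
            for s in PAIR_ORDER
        }
        dr = base.dr0 * np.sqrt(
            (rel["l_I"] * rel["l_II"]) / (rel["s_I"] * rel["s_II"])
        )
        return (dr - base.dr0) / base.dr_sigma
    slot = _slot_of(data_type)
    if base.sd_sigma[slot] <= 0:
        raise ValueError("undefined SNR: SD baseline noise is zero")
    delta = p_src * w_arrays[slot] * target_coeff
    return delta / base.sd_sigma[slot]


@dataclass
class SNRMap:
    """Signed SNR over the y=0 plane (x along rows, z along columns)."""

    values: np.ndarray  # (nx, nz)
    x: np.ndarray
    z: np.ndarray
    data_type: str
    af_kind: str


def snr_map(
    pairs: PairGrids,
    af: AFModel,
    target_coeff: float,
    noise_params: NoiseParams,
    p_src: float,
    data_type: str = "dr",
    noise_method: str = "sampling",
    n_draws: int = 10_000,
    seed: int = 0,
    base: BaselineState | None = None,
) -> SNRMap:
    """SNR to a point target at every y=0 voxel position."""
    if base is None:
        base = baseline_state(
            pairs, af, noise_params, p_src, noise_method, n_draws, seed
        )
    planes = _w_planes(pairs)
    values = _snr_from_w(planes, base, target_coeff, p_src, data_type)
    med = pairs.medium
    return SNRMap(
        values, med.axis_centers(0), med.axis_centers(2), data_type, af.kind
    )


def flow_trace(
    pairs: PairGrids,
    af: AFModel,
    target,
    noise_params: NoiseParams,
    p_src: float,
    data_type: str,
    positions: np.ndarray,
    noise_method: str = "sampling",
    n_draws: int = 10_000,
    seed: int = 0,
    base: BaselineState | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Signal (SNR units) vs time for a target moving along ``positions``.

    ``target`` is a TargetModel (its coefficient and velocity are used);
    ``positions`` is an (n, 3) array of target positions along the flow
    path.  The time axis is the cumulative path length divided by the flow
    speed.  Values agree with ``snr_map`` sampled at the same voxels.
    """
    positions = np.asarray(positions, dtype=float)
    med = pairs.medium
    for p in positions:
        if not med.contains(p):
            raise GeometryError(f"flow path leaves the medium at {p}")
    if base is None:
        base = baseline_state(
            pairs, af, noise_params, p_src, noise_method, n_draws, seed
        )
    w_at = {
        s: np.array([w.at(p) for p in positions])
        for s, w in pairs.slots.items()
    }
    values = _snr_from_w(w_at, base, target.coefficient, p_src, data_type)
    steps = np.linalg.norm(np.diff(positions, axis=0), axis=1)
    times = np.concatenate([[0.0], np.cumsum(steps)]) / target.velocity
    return times, values


@dataclass
class DepthScanResult:
    """SNR-vs-depth profiles and |SNR|>1 maximum depths per data type."""

    z: np.ndarray
    profiles: dict[str, np.ndarray]
    max_depth: dict[str, float | None]
    centroid_x: dict[str, float]


def _deepest_unity_crossing(z: np.ndarray, s: np.ndarray) -> float | None:
    """Deepest z with |SNR| > 1, linearly interpolated to |SNR| = 1."""
    a = np.abs(s)
    above = np.nonzero(a > 1.0)[0]
    if len(above) == 0:
        return None
    k = above[-1]
    if k == len(z) - 1:
        return float(z[-1])  # still above unity at the deepest grid point
    frac = (a[k] - 1.0) / (a[k] - a[k + 1])
    return float(z[k] + frac * (z[k + 1] - z[k]))


def depth_scan(
    pairs: PairGrids,
    af: AFModel,
    target_coeff: float,
    noise_params: NoiseParams,
    p_src: float,
    data_types: tuple[str, ...] = ("sd:s_I", "sd:l_I", "dr"),
    noise_method: str = "sampling",
    n_draws: int = 10_000,
    seed: int = 0,
    base: BaselineState | None = None,
) -> DepthScanResult:
    """SNR vs depth below each data type's optode centroid.

    The maximum measurable depth is where |SNR| falls below one, located by
    linear interpolation between the bracketing grid depths.
    """
    if base is None:
        base = baseline_state(
            pairs, af, noise_params, p_src, noise_method, n_draws, seed
        )
    med = pairs.medium
    z = med.axis_centers(2)
    profiles: dict[str, np.ndarray] = {}
    depths: dict[str, float | None] = {}
    cents: dict[str, float] = {}
    xc = med.axis_centers(0)
    iy = med.shape[1] // 2
    for dt in data_types:
        x0 = pairs.centroid_x(dt)
        ix = int(np.argmin(np.abs(xc - x0)))
        w_col = {s: w.values[ix, iy, :] for s, w in pairs.slots.items()}
        prof = _snr_from_w(w_col, base, target_coeff, p_src, dt)
        profiles[dt] = prof
        depths[dt] = (
            None if target_coeff == 0 else _deepest_unity_crossing(z, prof)
        )
        cents[dt] = x0
    return DepthScanResult(z, profiles, depths, cents)


@dataclass
class PncSweepResult:
    pnc_grid: np.ndarray
    max_depth: dict[str, list[float | None]]  # per data type, per pNC
    crossover_pnc: float | None  # largest pNC where DR beats the deepest SD


def pnc_sweep(
    pairs: PairGrids,
    af: AFModel,
    target_coeff: float,
    sigma_rel: float,
    p_src: float,
    pnc_grid,
    data_types: tuple[str, ...] = ("sd:s_I", "sd:l_I", "dr"),
    noise_method: str = "delta",
    n_draws: int = 10_000,
    seed: int = 0,
) -> PncSweepResult:
    """Maximum measurable depth per data type as a function of pNC.

    SD depths do not depend on pNC (the model keeps total SD noise fixed);
    the sweep repeats the DR depth scan across the grid with common random
    numbers and reports the largest pNC at which the DR depth still exceeds
    the deepest SD depth.
    """
    pnc_grid = np.asarray(pnc_grid, dtype=float)
    if np.any((pnc_grid < 0) | (pnc_grid > 1)):
        raise ValueError("pnc values must lie in [0, 1]")
    results: dict[str, list[float | None]] = {dt: [] for dt in data_types}
    sd_types = [dt for dt in data_types if dt != "dr"]
    for pnc in pnc_grid:
        params = NoiseParams(sigma_rel=sigma_rel, p_nc=float(pnc))
        scan = depth_scan(
            pairs,
            af,
            target_coeff,
            params,
            p_src,
            data_types,
            noise_method,
            n_draws,
            seed,  # common random numbers across the sweep
        )
        for dt in data_types:
            results[dt].append(scan.max_depth[dt])
    crossover = None
    if "dr" in data_types and sd_types:
        order = np.argsort(pnc_grid)
        for i, pnc in zip(order, pnc_grid[order]):
            sd_best = max(
                (results[dt][i] or 0.0) for dt in sd_types
            )
            dr_depth = results["dr"][i] or 0.0
            if dr_depth > sd_best:
                crossover = float(pnc)
    return PncSweepResult(pnc_grid, results, crossover)
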