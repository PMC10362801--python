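"""Named end-to-end workflows chaining the library modules.

Each workflow reads/writes files in a working directory so that runs are
resumable and every artifact carries the config hash and seeds that
produced it.  Missing upstream artifacts raise a DependencyError naming
the file.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gridio
from .calibrate import Trace, calibrate_trace
from .config import RunConfig
from .experiments import (
    PairGrids,
    build_pair_grids,
    depth_scan,
    flow_trace,
    pnc_sweep,
    snr_map,
)
from .synthfix import PeakSchedule, make_trace
from .transport import run_photon_mc

__all__ = ["DependencyError", "run_pipeline", "WORKFLOWS"]

OPTODE_NAMES = ("1", "2", "A", "B")


class DependencyError(FileNotFoundError):
    """A workflow is missing an upstream artifact."""


def _atomic_write_json(payload: dict, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    with os.fdopen(fd, "w") as fh:
        json.dump(payload, fh, indent=2)
    os.replace(tmp, path)


def _provenance(cfg: RunConfig) -> dict:
    return {"config_hash": cfg.config_hash(), "seed": cfg.seed,
            "n_photons": cfg.n_photons}


def _fluence_path(workdir: Path, name: str) -> Path:
    return workdir / f"fluence_{name}.h5"


def workflow_fluence(cfg: RunConfig, workdir: Path) -> list[Path]:
    """Run the MC once per optode and persist the four fluence grids."""
    geom = cfg.geometry
    optodes = {**geom.sources, **geom.detectors}
    out = []
    for i, (name, optode) in enumerate(sorted(optodes.items())):
        grid = run_photon_mc(
            cfg.medium, optode, cfg.n_photons, cfg.seed + i, cfg.gates
        )
        path = _fluence_path(workdir, name)
        gridio.save_fluence(grid, path, extra_attrs=_provenance(cfg))
        out.append(path)
    return out


def _load_fluences(cfg: RunConfig, workdir: Path) -> dict:
    fluences = {}
    names = sorted({**cfg.geometry.sources, **cfg.geometry.detectors})
    for name in names:
        path = _fluence_path(workdir, name)
        if not path.exists():
            raise DependencyError(
                f"missing fluence file {path}; run the 'fluence' workflow first"
            )
        fluences[name] = gridio.load_fluence(path)
    return fluences


def workflow_jacobian(cfg: RunConfig, workdir: Path) -> list[Path]:
    """Build and persist the four pair Jacobians from the fluence files."""
    pairs = build_pair_grids(_load_fluences(cfg, workdir), cfg.geometry)
    out = []
    for slot, w in pairs.slots.items():
        path = workdir / f"jacobian_{slot}.h5"
        gridio.save_sensitivity(w, path, extra_attrs=_provenance(cfg))
        out.append(path)
    return out


def _load_pairs(cfg: RunConfig, workdir: Path) -> PairGrids:
    from .measurements import validate_dr_layout

    valid, assignment, diag = validate_dr_layout(cfg.geometry)
    if not valid:
        raise ValueError(f"invalid DR layout: {diag}")
    slots = {}
    for slot in assignment:
        path = workdir / f"jacobian_{slot}.h5"
        if not path.exists():
            raise DependencyError(
                f"missing jacobian file {path}; run the 'jacobian' workflow first"
            )
        slots[slot] = gridio.load_sensitivity(path)
    return PairGrids(slots, cfg.geometry, assignment)


def workflow_snr_map(cfg: RunConfig, workdir: Path) -> Path:
    pairs = _load_pairs(cfg, workdir)
    out = workdir / "snr_maps.json"
    maps = {}
    for dt in ("sd:s_I", "sd:l_I", "dr"):
        m = snr_map(
            pairs, cfg.af, cfg.target.coefficient, cfg.noise, cfg.p_src,
            data_type=dt, seed=cfg.seed,
        )
        maps[dt] = {
            "x_mm": m.x.tolist(),
            "z_mm": m.z.tolist(),
            "snr": np.round(m.values, 4).tolist(),
        }
    _atomic_write_json({**_provenance(cfg), "af_kind": cfg.af.kind,
                        "maps": maps}, out)
    return out


def workflow_trace(cfg: RunConfig, workdir: Path) -> Path:
    """Simulated flow trace of a target moving parallel to the optode line."""
    pairs = _load_pairs(cfg, workdir)
    med = pairs.medium
    depth = cfg.target.position[2]
    x = med.axis_centers(0)
    keep = np.abs(x) <= 8.0
    positions = np.column_stack(
        [x[keep], np.zeros(keep.sum()), np.full(keep.sum(), depth)]
    )
    out = workdir / "flow_trace.csv"
    frames = {}
    for dt in ("sd:s_I", "sd:l_I", "dr"):
        times, values = flow_trace(
            pairs, cfg.af, cfg.target, cfg.noise, cfg.p_src, dt, positions,
            seed=cfg.seed,
        )
        frames[dt] = values
    df = pd.DataFrame({"time_s": times, "x_mm": positions[:, 0], **frames})
    df.to_csv(out, index=False)
    return out


def workflow_depth_scan(cfg: RunConfig, workdir: Path) -> Path:
    pairs = _load_pairs(cfg, workdir)
    scan = depth_scan(
        pairs, cfg.af, cfg.target.coefficient, cfg.noise, cfg.p_src,
        seed=cfg.seed,
    )
    out = workdir / "depth_scan.csv"
    rows = [
        {
            "data_type": dt,
            "centroid_x_mm": scan.centroid_x[dt],
            "max_depth_mm": scan.max_depth[dt],
        }
        for dt in scan.profiles
    ]
    pd.DataFrame(rows).to_csv(out, index=False)
    _atomic_write_json(
        {**_provenance(cfg), "af_kind": cfg.af.kind,
         "max_depth_mm": {k: scan.max_depth[k] for k in scan.profiles}},
        workdir / "depth_scan.json",
    )
    return out


def workflow_pnc_sweep(cfg: RunConfig, workdir: Path) -> Path:
    pairs = _load_pairs(cfg, workdir)
    grid = np.round(np.arange(0.02, 1.0001, 0.02), 4)
    sweep = pnc_sweep(
        pairs, cfg.af, cfg.target.coefficient, cfg.noise.sigma_rel,
        cfg.p_src, grid, seed=cfg.seed,
    )
    out = workdir / "pnc_sweep.json"
    _atomic_write_json(
        {
            **_provenance(cfg),
            "af_kind": cfg.af.kind,
            "pnc": sweep.pnc_grid.tolist(),
            "max_depth_mm": sweep.max_depth,
            "crossover_pnc": sweep.crossover_pnc,
        },
        out,
    )
    return out


def workflow_simulate_trace(cfg: RunConfig, workdir: Path) -> Path:
    """Synthetic phantom-style trace with a JSON ground-truth sidecar."""
    duration, n_peaks, amp = 60.0, 20, 47.3
    background = 170.0
    schedule = PeakSchedule.regular(n_peaks, amp, duration)
    trace = make_trace(
        background, cfg.noise.sigma_rel, schedule, duration, seed=cfg.seed
    )
    out = workdir / "synthetic_trace.csv"
    trace.to_csv(out)
    _atomic_write_json(
        {
            **_provenance(cfg),
            "background_nA": background,
            "sigma_rel": cfg.noise.sigma_rel,
            "n_peaks": n_peaks,
            "peak_amplitude_nA": amp,
            "duration_s": duration,
        },
        workdir / "synthetic_trace_truth.json",
    )
    return out


def workflow_calibrate(cfg: RunConfig, workdir: Path) -> Path:
    trace_path = workdir / "synthetic_trace.csv"
    if not trace_path.exists():
        raise DependencyError(
            f"missing trace file {trace_path}; run 'simulate-trace' first"
        )
    trace = Trace.from_csv(trace_path)
    w = None
    jac = workdir / "jacobian_s_I.h5"
    if jac.exists():
        w = gridio.load_sensitivity(jac)
    result = calibrate_trace(trace, cfg.conversion, w=w, p_src=cfg.p_src)
    out = workdir / "calibration.json"
    _atomic_write_json({**_provenance(cfg), **result.to_dict()}, out)
    return out


def workflow_full_chain(cfg: RunConfig, workdir: Path) -> Path:
    """Full chain: fluence ×4 → jacobian ×4 → depth scan table."""
    workflow_fluence(cfg, workdir)
    workflow_jacobian(cfg, workdir)
    return workflow_depth_scan(cfg, workdir)


WORKFLOWS = {
    "fluence": workflow_fluence,
    "jacobian": workflow_jacobian,
    "snr-map": workflow_snr_map,
    "trace": workflow_trace,
    "depth-scan": workflow_depth_scan,
    "pnc-sweep": workflow_pnc_sweep,
    "simulate-trace": workflow_simulate_trace,
    "calibrate": workflow_calibrate,
    "full-chain": workflow_full_chain,
}


def run_pipeline(cfg: RunConfig, workflow: str, workdir) -> object:
    """Execute a named workflow in ``workdir`` and return its output path(s)."""
    if workflow not in WORKFLOWS:
        raise ValueError(
            f"unknown workflow {workflow!r}; choose from {sorted(WORKFLOWS)}"
        )
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    return WORKFLOWS[workflow](cfg, workdir)
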