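"""HDF5 persistence for fluence and sensitivity grids."""

from __future__ import annotations

import h5py
import numpy as np

from .fluorescence import SensitivityGrid
from .transport import FluenceGrid, OpticalMedium, OptodeSpec, TimeGates

__all__ = [
    "save_fluence",
    "load_fluence",
    "save_sensitivity",
    "load_sensitivity",
]


def _write_medium_attrs(g, medium: OpticalMedium) -> None:
    g.attrs["voxel_mm"] = medium.voxel
    g.attrs["extent_mm"] = np.asarray(medium.extent)
    g.attrs["mu_a"] = medium.mu_a
    g.attrs["mu_s"] = medium.mu_s
    g.attrs["g"] = medium.g
    g.attrs["n_in"] = medium.n_in
    g.attrs["n_out"] = medium.n_out


def _read_medium_attrs(g) -> OpticalMedium:
    return OpticalMedium(
        mu_a=float(g.attrs["mu_a"]),
        mu_s=float(g.attrs["mu_s"]),
        g=float(g.attrs["g"]),
        n_in=float(g.attrs["n_in"]),
        n_out=float(g.attrs["n_out"]),
        extent=tuple(float(e) for e in g.attrs["extent_mm"]),
        voxel=float(g.attrs["voxel_mm"]),
    )


def save_fluence(grid: FluenceGrid, path, extra_attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("fluence", data=grid.values)
        _write_medium_attrs(ds, grid.medium)
        ds.attrs["n_photons"] = grid.n_photons
        ds.attrs["seed"] = grid.seed
        ds.attrs["optode_role"] = grid.optode.role
        ds.attrs["beam"] = grid.optode.beam
        ds.attrs["na"] = grid.optode.na
        ds.attrs["position_mm"] = np.asarray(grid.optode.position)
        ds.attrs["n_gates"] = grid.gates.n_gates
        ds.attrs["t_end_ns"] = grid.gates.t_end_ns
        for k, v in (extra_attrs or {}).items():
            ds.attrs[k] = v


def load_fluence(path) -> FluenceGrid:
    with h5py.File(path, "r") as f:
        ds = f["fluence"]
        medium = _read_medium_attrs(ds)
        optode = OptodeSpec(
            position=tuple(float(p) for p in ds.attrs["position_mm"]),
            role=str(ds.attrs["optode_role"]),
            beam=str(ds.attrs["beam"]),
            na=float(ds.attrs["na"]),
        )
        gates = TimeGates(
            int(ds.attrs["n_gates"]), float(ds.attrs["t_end_ns"])
        )
        return FluenceGrid(
            ds[...],
            medium,
            optode,
            int(ds.attrs["n_photons"]),
            int(ds.attrs["seed"]),
            gates,
        )


def save_sensitivity(
    grid: SensitivityGrid, path, extra_attrs: dict | None = None
) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("sensitivity", data=grid.values)
        _write_medium_attrs(ds, grid.medium)
        ds.attrs["pair_src"] = grid.pair[0]
        ds.attrs["pair_det"] = grid.pair[1]
        for k, v in (extra_attrs or {}).items():
            ds.attrs[k] = v


def load_sensitivity(path) -> SensitivityGrid:
    with h5py.File(path, "r") as f:
        ds = f["sensitivity"]
        return SensitivityGrid(
            ds[...],
            _read_medium_attrs(ds),
            (str(ds.attrs["pair_src"]), str(ds.attrs["pair_det"])),
        )
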