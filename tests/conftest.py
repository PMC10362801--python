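"""Shared fixtures.

The two session-scoped Monte-Carlo fixtures are the expensive ones: they
are computed once and reused by every test that needs physically realistic
sensitivity grids.  Their problem sizes are the package's desk-scale study
conditions (documented in docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pytest

from drdifc.experiments import build_pair_grids
from drdifc.measurements import default_geometry
from drdifc.synthfix import make_toy_grids
from drdifc.transport import OpticalMedium, OptodeSpec, run_photon_mc


@pytest.fixture(scope="session")
def desk_medium() -> OpticalMedium:
    return OpticalMedium(extent=(30.0, 30.0, 15.0), voxel=0.25)


@pytest.fixture(scope="session")
def fine_pairs(desk_medium):
    """Four-optode sensitivity grids at the desk-scale study conditions."""
    geom = default_geometry()
    optodes = sorted({**geom.sources, **geom.detectors}.items())
    fluences = {
        name: run_photon_mc(desk_medium, o, 4_000_000, seed=100 + i)
        for i, (name, o) in enumerate(optodes)
    }
    return build_pair_grids(fluences, geom)


@pytest.fixture(scope="session")
def mc_fluence_10m():
    """Pencil-beam fluence at 10⁷ photons for transport validation."""
    med = OpticalMedium(extent=(20.0, 20.0, 10.0), voxel=0.25)
    src = OptodeSpec((0.0, 0.0, 0.0), role="source", beam="pencil")
    return med, run_photon_mc(med, src, 10_000_000, seed=11)


@pytest.fixture()
def toy_uniform():
    return make_toy_grids((4, 4, 4), "uniform", voxel=1.0, values=(2.0, 3.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
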