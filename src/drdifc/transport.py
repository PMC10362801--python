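"""Photon-transport Green's functions on a voxel grid.

The forward model everything else builds on: a native Monte-Carlo kernel
for a homogeneous slab (pencil-beam sources, NA-cone detectors launched as
adjoint sources) plus a semi-infinite diffusion-theory closed form that
serves as fallback and as an independent oracle for the MC.

Conventions
-----------
* The tissue surface is the z = 0 plane, z positive into the medium; x and
  y are centered so the lateral faces sit at ±extent/2.
* The top face applies Fresnel reflection/refraction (``n_in`` against
  ``n_out``); the other five faces are absorbing.
* Time-gated grids store fluence *per unit time* (mm⁻² ns⁻¹); the
  continuous-wave grid is the gate-width-weighted sum (mm⁻² per unit
  source power), i.e. a Green's function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels

__all__ = [
    "OpticalMedium",
    "OptodeSpec",
    "TimeGates",
    "FluenceGrid",
    "TimeGatedFluence",
    "WeightTally",
    "run_photon_mc",
    "run_photon_mc_gated",
    "cw_integrate",
    "diffusion_green",
    "GeometryError",
]


class GeometryError(ValueError):
    """A position or optode violates the medium geometry."""


@dataclass(frozen=True)
class OpticalMedium:
    """Homogeneous voxelized slab with its optical properties.

    Parameters
    ----------
    mu_a, mu_s : float
        Absorption and scattering coefficients, mm⁻¹.
    g : float
        Henyey-Greenstein scattering anisotropy, dimensionless.
    n_in, n_out : float
        Interior and exterior refractive indices.
    extent : tuple of float
        Side lengths (x, y, z) in mm; each must be an integer multiple of
        ``voxel``.
    voxel : float
        Cubic voxel edge length, mm.
    """

    mu_a: float = 0.002
    mu_s: float = 7.0
    g: float = 0.9
    n_in: float = 1.37
    n_out: float = 1.0
    extent: tuple[float, float, float] = (30.0, 30.0, 30.0)
    voxel: float = 0.1

    def __post_init__(self):
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s <= 0:
            raise ValueError(f"mu_s must be > 0, got {self.mu_s}")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError(f"g must be in [-1, 1], got {self.g}")
        if self.n_in < 1.0 or self.n_out < 1.0:
            raise ValueError("refractive indices must be >= 1")
        if self.voxel <= 0:
            raise ValueError(f"voxel must be > 0, got {self.voxel}")
        if len(self.extent) != 3:
            raise ValueError("extent must have three side lengths")
        for e in self.extent:
            ratio = e / self.voxel
            if e <= 0 or abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(
                    f"extent {e} mm is not a positive integer multiple of "
                    f"voxel {self.voxel} mm"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(int(round(e / self.voxel)) for e in self.extent)

    @property
    def mu_t(self) -> float:
        return self.mu_a + self.mu_s

    @property
    def mu_s_reduced(self) -> float:
        return self.mu_s * (1.0 - self.g)

    @property
    def voxel_volume(self) -> float:
        return self.voxel**3

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along ``axis`` (0=x, 1=y, 2=z), mm."""
        n = self.shape[axis]
        edges = np.arange(n) * self.voxel
        if axis < 2:
            return edges + self.voxel / 2 - self.extent[axis] / 2
        return edges + self.voxel / 2

    def contains(self, position) -> bool:
        x, y, z = position
        return (
            abs(x) <= self.extent[0] / 2
            and abs(y) <= self.extent[1] / 2
            and 0.0 <= z <= self.extent[2]
        )

    def voxel_index(self, position) -> tuple[int, int, int]:
        """Nearest-voxel index of an interior position."""
        if not self.contains(position):
            raise GeometryError(f"position {position} outside medium")
        x, y, z = position
        nx, ny, nz = self.shape
        ix = min(int((x + self.extent[0] / 2) / self.voxel), nx - 1)
        iy = min(int((y + self.extent[1] / 2) / self.voxel), ny - 1)
        iz = min(int(z / self.voxel), nz - 1)
        return ix, iy, iz


@dataclass(frozen=True)
class OptodeSpec:
    """A source or detector fiber position on the z = 0 surface.

    Detectors are modeled, via the adjoint method, as cone-beam sources
    with the fiber's numerical aperture (defined in the exterior medium);
    sources are normally-incident pencil beams.
    """

    position: tuple[float, float, float]
    role: str = "source"  # 'source' | 'detector'
    beam: str = "pencil"  # 'pencil' | 'cone'
    na: float = 0.5

    def __post_init__(self):
        if self.role not in ("source", "detector"):
            raise ValueError(f"role must be source or detector, got {self.role}")
        if self.beam not in ("pencil", "cone"):
            raise ValueError(f"beam must be pencil or cone, got {self.beam}")
        if len(self.position) != 3:
            raise ValueError("position must be a 3-vector")
        if abs(self.position[2]) > 1e-9:
            raise GeometryError(
                f"optode must sit on the z=0 surface, got z={self.position[2]}"
            )
        if self.beam == "cone" and not 0.0 < self.na < 1.0 * 10:
            raise ValueError(f"NA must be positive, got {self.na}")

    def validate_on(self, medium: OpticalMedium) -> None:
        x, y, _ = self.position
        if abs(x) > medium.extent[0] / 2 or abs(y) > medium.extent[1] / 2:
            raise GeometryError(
                f"optode at {self.position} outside the lateral extent"
            )
        if self.beam == "cone" and self.na >= medium.n_out:
            raise ValueError(
                f"NA {self.na} not physically admissible for n_out={medium.n_out}"
            )


@dataclass(frozen=True)
class TimeGates:
    """Uniform time gates for time-resolved scoring."""

    n_gates: int = 10
    t_end_ns: float = 10.0

    def __post_init__(self):
        if self.n_gates < 1 or self.t_end_ns <= 0:
            raise ValueError("need n_gates >= 1 and t_end_ns > 0")

    @property
    def width_ns(self) -> float:
        return self.t_end_ns / self.n_gates


@dataclass(frozen=True)
class WeightTally:
    """Terminal photon-weight bookkeeping for one MC run."""

    launched: float
    escaped_top: float
    escaped_other: float
    absorbed: float
    expired: float
    roulette_killed: float

    @property
    def accounted(self) -> float:
        return (
            self.escaped_top
            + self.escaped_other
            + self.absorbed
            + self.expired
            + self.roulette_killed
        )


@dataclass
class TimeGatedFluence:
    """Time-gated fluence Green's function, mm⁻² ns⁻¹ per gate."""

    values: np.ndarray  # (n_gates, nx, ny, nz)
    gates: TimeGates
    medium: OpticalMedium
    optode: OptodeSpec
    n_photons: int
    seed: int


@dataclass
class FluenceGrid:
    """Continuous-wave fluence Green's function map, mm⁻²."""

    values: np.ndarray  # (nx, ny, nz)
    medium: OpticalMedium
    optode: OptodeSpec
    n_photons: int
    seed: int
    gates: TimeGates = field(default_factory=TimeGates)

    def at(self, position) -> float:
        return float(self.values[self.medium.voxel_index(position)])


def run_photon_mc_gated(
    medium: OpticalMedium,
    optode: OptodeSpec,
    n_photons: int,
    seed: int,
    gates: TimeGates = TimeGates(),
) -> tuple[TimeGatedFluence, WeightTally]:
    """Run the MC kernel and return the time-gated fluence plus tallies.

    The returned grid is normalized per launched unit power and per unit
    time; for a medium with ``mu_a == 0`` the fluence cannot be recovered
    from the absorption estimator and the grid is all zeros (the weight
    tally is still exact, which is what the conservation check uses).
    """
    if n_photons < 1:
        raise ValueError(f"n_photons must be >= 1, got {n_photons}")
    optode.validate_on(medium)
    nx, ny, nz = medium.shape
    deposit = np.zeros((gates.n_gates, nx, ny, nz), dtype=np.float64)
    tally = np.zeros(5, dtype=np.float64)
    _kernels.run_mc(
        deposit,
        tally,
        int(n_photons),
        int(seed),
        medium.mu_a,
        medium.mu_s,
        medium.g,
        medium.n_in,
        medium.n_out,
        medium.extent[0],
        medium.extent[1],
        medium.extent[2],
        medium.voxel,
        optode.position[0],
        optode.position[1],
        optode.beam == "cone",
        optode.na,
        gates.n_gates,
        gates.t_end_ns,
    )
    if medium.mu_a > 0:
        norm = n_photons * medium.mu_a * medium.voxel_volume * gates.width_ns
        values = deposit / norm
    else:
        values = deposit  # all zeros: nothing was absorbed
    wt = WeightTally(
        launched=float(n_photons),
        escaped_top=tally[_kernels.TALLY_ESCAPED_TOP],
        escaped_other=tally[_kernels.TALLY_ESCAPED_OTHER],
        absorbed=tally[_kernels.TALLY_ABSORBED],
        expired=tally[_kernels.TALLY_EXPIRED],
        roulette_killed=tally[_kernels.TALLY_ROULETTE],
    )
    gated = TimeGatedFluence(values, gates, medium, optode, n_photons, seed)
    return gated, wt


def run_photon_mc(
    medium: OpticalMedium,
    optode: OptodeSpec,
    n_photons: int,
    seed: int,
    gates: TimeGates = TimeGates(),
) -> FluenceGrid:
    """Time-integrated (CW) fluence Green's function for one optode."""
    gated, _ = run_photon_mc_gated(medium, optode, n_photons, seed, gates)
    return cw_integrate(gated, gates)


def cw_integrate(gated: TimeGatedFluence, gates: TimeGates | None = None) -> FluenceGrid:
    """Integrate a per-unit-time gated grid over its gates: CW = Σ value·Δt."""
    if gates is None:
        gates = gated.gates
    if gates != gated.gates or gated.values.shape[0] != gates.n_gates:
        raise ValueError("gate spec inconsistent with the gated grid")
    cw = gated.values.sum(axis=0) * gates.width_ns
    return FluenceGrid(
        cw, gated.medium, gated.optode, gated.n_photons, gated.seed, gates
    )


def _effective_reflection_parameter(n_rel: float) -> float:
    """Groenhuis/Egan internal-reflection parameter A = (1+Reff)/(1-Reff)."""
    r_eff = -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    return (1.0 + r_eff) / (1.0 - r_eff)


def diffusion_green(
    medium: OpticalMedium,
    src_position,
    field_position,
) -> float:
    """Semi-infinite diffusion-theory CW Green's function, mm⁻².

    A normally-incident pencil beam is represented as an isotropic point
    source buried one transport mean free path below the surface; the
    extrapolated-boundary condition is imposed with a single negative image
    source.  Used as the analytic fallback and as the independent oracle
    for the MC kernel.
    """
    if medium.mu_s_reduced <= 0:
        raise ValueError("diffusion theory needs mu_s(1-g) > 0")
    fx, fy, fz = field_position
    if not medium.contains(field_position) or fz <= 0:
        raise GeometryError(f"field position {field_position} outside medium")
    sx, sy, _ = src_position
    mu_tr = medium.mu_a + medium.mu_s_reduced
    d_coeff = 1.0 / (3.0 * mu_tr)
    mu_eff = math.sqrt(medium.mu_a / d_coeff)
    z0 = 1.0 / mu_tr
    zb = 2.0 * _effective_reflection_parameter(medium.n_in / medium.n_out) * d_coeff
    rho2 = (fx - sx) ** 2 + (fy - sy) ** 2
    r1 = math.sqrt(rho2 + (fz - z0) ** 2)
    r2 = math.sqrt(rho2 + (fz + z0 + 2.0 * zb) ** 2)
    return (
        math.exp(-mu_eff * r1) / r1 - math.exp(-mu_eff * r2) / r2
    ) / (4.0 * math.pi * d_coeff)
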