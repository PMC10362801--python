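"""Fluorescence Jacobian and reflectance forward model.

The detected fluorescent reflectance from a point fluorophore is, per unit
source power, the product of the excitation fluence Green's function at the
fluorophore, the (adjoint) detection Green's function, the voxel volume and
the fluorophore's absorption-efficiency product μa·η.  The spatial part is
collected into the fluorescence Jacobian

    W(r) = Φ_src(r) · Φ_det(r) · V        [mm⁻¹]

so a point target contributes ``Psrc · W(r_t) · μa,t·η_t`` and a distributed
autofluorescence (AF) background contributes ``Psrc · Σ_r W(r)·μa,AF(r)·η_AF(r)``.
Excitation and emission optical properties are assumed equal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transport import FluenceGrid, GeometryError, OpticalMedium

__all__ = [
    "AFModel",
    "TargetModel",
    "SensitivityGrid",
    "ReflectanceValue",
    "sensitivity_map",
    "target_reflectance",
    "background_reflectance",
    "total_reflectance",
]


@dataclass(frozen=True)
class AFModel:
    """Autofluorescence contributor distribution.

    ``surface_weighted`` halves the contribution per ``half_depth`` mm of
    depth (profile 2^(−z/half_depth)); ``homogeneous`` is constant.  The
    ``coefficient`` is the μa,AF·ηAF prefactor in mm⁻¹.
    """

    kind: str = "surface_weighted"  # or 'homogeneous'
    coefficient: float = 228e-9
    half_depth: float = 0.1

    def __post_init__(self):
        if self.kind not in ("surface_weighted", "homogeneous"):
            raise ValueError(f"unknown AF kind {self.kind!r}")
        if self.coefficient < 0:
            raise ValueError("AF coefficient must be >= 0")
        if self.half_depth <= 0:
            raise ValueError("half_depth must be > 0")

    def profile(self, z: np.ndarray) -> np.ndarray:
        """μa,AF·ηAF at depth(s) z (mm)."""
        z = np.asarray(z, dtype=float)
        if self.kind == "homogeneous":
            return np.full_like(z, self.coefficient)
        return self.coefficient * np.exp2(-z / self.half_depth)


@dataclass(frozen=True)
class TargetModel:
    """A point fluorescent target (e.g. a labeled circulating cell)."""

    coefficient: float = 43.3e-6  # μa,target·ηtarget, mm⁻¹
    position: tuple[float, float, float] = (0.0, 0.0, 1.5)
    velocity: float = 25.0  # mm/s, for flow traces
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self):
        if self.coefficient < 0:
            raise ValueError("target coefficient must be >= 0")


@dataclass
class SensitivityGrid:
    """Fluorescence Jacobian W (mm⁻¹) for one source-detector pair."""

    values: np.ndarray
    medium: OpticalMedium
    pair: tuple[str, str] = ("src", "det")

    @property
    def voxel_volume(self) -> float:
        return self.medium.voxel_volume

    def at(self, position) -> float:
        """Nearest-voxel W at a position (grid convention of the MC)."""
        return float(self.values[self.medium.voxel_index(position)])

    def at_interpolated(self, position) -> float:
        """Trilinearly interpolated W, for smooth flow traces."""
        med = self.medium
        if not med.contains(position):
            raise GeometryError(f"position {position} outside medium")
        coords = []
        for axis, p in enumerate(position):
            centers = med.axis_centers(axis)
            coords.append(np.interp(p, centers, np.arange(len(centers))))
        from scipy.ndimage import map_coordinates

        return float(
            map_coordinates(self.values, np.array(coords)[:, None], order=1)[0]
        )


def sensitivity_map(phi_src: FluenceGrid, phi_det: FluenceGrid) -> SensitivityGrid:
    """Per-voxel product of the two fluence maps times the voxel volume."""
    if phi_src.medium != phi_det.medium:
        raise ValueError("fluence grids computed on different media")
    if phi_src.values.shape != phi_det.values.shape:
        raise ValueError("fluence grid shapes differ")
    med = phi_src.medium
    w = phi_src.values * phi_det.values * med.voxel_volume
    pair = (_optode_name(phi_src), _optode_name(phi_det))
    return SensitivityGrid(w, med, pair)


def _optode_name(grid: FluenceGrid) -> str:
    o = grid.optode
    return f"{o.role}@({o.position[0]:g},{o.position[1]:g})"


def target_reflectance(
    w: SensitivityGrid, target: TargetModel, p_src: float, interpolate: bool = False
) -> float:
    """Point-target fluorescent reflectance Psrc·W(r_t)·μa,t·η_t, mW mm⁻²."""
    if target.coefficient == 0:
        # still validate geometry for a consistent error contract
        w.medium.voxel_index(target.position)
        return 0.0
    w_at = (
        w.at_interpolated(target.position) if interpolate else w.at(target.position)
    )
    return p_src * w_at * target.coefficient


def background_reflectance(w: SensitivityGrid, af: AFModel, p_src: float) -> float:
    """Distributed-AF background reflectance R0 = Psrc·Σ W·μa,AF·ηAF, mW mm⁻²."""
    z = w.medium.axis_centers(2)
    profile = af.profile(z)  # depends on depth only
    return float(p_src * np.sum(w.values * profile[None, None, :]))


@dataclass(frozen=True)
class ReflectanceValue:
    """Total fluorescent reflectance split into background and target parts."""

    background: float
    target: float
    source_power: float

    @property
    def value(self) -> float:
        return self.background + self.target


def total_reflectance(
    w: SensitivityGrid,
    af: AFModel,
    target: TargetModel,
    p_src: float,
    interpolate: bool = False,
) -> ReflectanceValue:
    """Background plus point-target reflectance, components kept separate."""
    r0 = background_reflectance(w, af, p_src)
    rt = target_reflectance(w, target, p_src, interpolate=interpolate)
    return ReflectanceValue(background=r0, target=rt, source_power=p_src)
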