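"""Synthetic traces and toy grids with known ground truth.

Everything here exists so the rest of the package is testable without any
external data: a detector-current trace generator whose statistical
structure matches the calibration model (multiplicative relative Gaussian
noise on a constant baseline, plus scheduled transient peaks), and tiny
fluence/sensitivity grids with closed-form values.

Note the noise convention: samples are ``baseline · (1 + N(0, σrel))``,
i.e. *multiplicative relative* noise matching σrel = σI/R — not additive
absolute noise.  Both conventions exist in the field; this package uses
the multiplicative one throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibrate import Trace
from .fluorescence import SensitivityGrid, sensitivity_map
from .transport import FluenceGrid, OpticalMedium, OptodeSpec, TimeGates

__all__ = ["PeakEvent", "PeakSchedule", "make_trace", "make_toy_grids"]


@dataclass(frozen=True)
class PeakEvent:
    """One transient peak: a cell transit through the sensitivity region."""

    time_s: float
    amplitude_na: float
    width_ms: float = 10.0
    shape: str = "gaussian"  # or 'doublet'

    def __post_init__(self):
        if self.width_ms <= 0:
            raise ValueError("peak width must be > 0")


@dataclass(frozen=True)
class PeakSchedule:
    events: tuple[PeakEvent, ...] = ()

    @classmethod
    def regular(
        cls,
        n_peaks: int,
        amplitude_na: float,
        duration_s: float,
        width_ms: float = 10.0,
        start_s: float = 1.5,
    ) -> "PeakSchedule":
        """Evenly spaced identical peaks across the trace."""
        if n_peaks == 0:
            return cls(())
        times = np.linspace(start_s, duration_s - start_s, n_peaks)
        return cls(
            tuple(PeakEvent(float(t), amplitude_na, width_ms) for t in times)
        )

    def validate(self, duration_s: float) -> None:
        for ev in self.events:
            if not 0.0 <= ev.time_s <= duration_s:
                raise ValueError(
                    f"peak at {ev.time_s} s outside the {duration_s} s trace"
                )


def _doublet_waveform(t: np.ndarray, t0: float, width_s: float) -> np.ndarray:
    """Asymmetric two-lobe transit waveform (source lobe higher)."""
    sep = 1.5 * width_s
    lobe1 = 0.65 * np.exp(-0.5 * ((t - t0 + sep / 2) / (width_s / 2)) ** 2)
    lobe2 = np.exp(-0.5 * ((t - t0 - sep / 2) / (width_s / 2)) ** 2)
    return lobe1 + lobe2


def make_trace(
    background: float,
    sigma_rel: float,
    schedule: PeakSchedule,
    duration: float,
    sample_rate: float = 2000.0,
    seed: int = 0,
) -> Trace:
    """Generate a synthetic detector-current trace, nA.

    Samples are baseline·(1 + N(0, σrel)) plus the scheduled peak
    waveforms; deterministic for a fixed seed, with exactly
    ``round(duration·sample_rate)`` samples.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if background < 0:
        raise ValueError("background must be >= 0")
    if sigma_rel < 0:
        raise ValueError("sigma_rel must be >= 0")
    schedule.validate(duration)
    n = int(round(duration * sample_rate))
    rng = np.random.default_rng(seed)
    y = background * (1.0 + sigma_rel * rng.standard_normal(n))
    t = np.arange(n) / sample_rate
    for ev in schedule.events:
        w_s = ev.width_ms / 1000.0
        if ev.shape == "doublet":
            y += ev.amplitude_na * _doublet_waveform(t, ev.time_s, w_s)
        else:
            y += ev.amplitude_na * np.exp(
                -0.5 * ((t - ev.time_s) / (w_s / 2.355)) ** 2
            )
    return Trace(y, sample_rate=sample_rate)


def make_toy_grids(
    shape: tuple[int, int, int] = (4, 4, 4),
    pattern: str = "uniform",
    voxel: float = 1.0,
    values: tuple[float, float] = (2.0, 3.0),
) -> tuple[FluenceGrid, FluenceGrid, SensitivityGrid]:
    """Tiny fluence-grid pair and their Jacobian with closed-form values.

    Patterns: ``uniform`` (constants a and b so W = a·b·V everywhere),
    ``point`` (a single non-zero voxel in each grid, co-located, so W is
    non-zero in exactly one voxel), ``separable`` (axis-separable ramps so
    sums factor into per-axis products).
    """
    if any(s < 1 for s in shape) or any(s > 32 for s in shape):
        raise ValueError("toy grid shape must be within 1..32 per axis")
    medium = OpticalMedium(
        extent=tuple(s * voxel for s in shape), voxel=voxel
    )
    a, b = values
    if pattern == "uniform":
        va = np.full(shape, float(a))
        vb = np.full(shape, float(b))
    elif pattern == "point":
        va = np.zeros(shape)
        vb = np.zeros(shape)
        center = tuple(s // 2 for s in shape)
        va[center] = a
        vb[center] = b
    elif pattern == "separable":
        ax = [np.arange(1.0, s + 1.0) for s in shape]
        va = a * ax[0][:, None, None] * ax[1][None, :, None] * ax[2][None, None, :]
        vb = b * np.ones(shape)
    else:
        raise ValueError(f"unknown toy pattern {pattern!r}")
    src = OptodeSpec((0.0, 0.0, 0.0), role="source", beam="pencil")
    det = OptodeSpec((0.0, 0.0, 0.0), role="detector", beam="cone", na=0.5)
    gates = TimeGates()
    phi_src = FluenceGrid(va, medium, src, n_photons=0, seed=0, gates=gates)
    phi_det = FluenceGrid(vb, medium, det, n_photons=0, seed=0, gates=gates)
    return phi_src, phi_det, sensitivity_map(phi_src, phi_det)
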