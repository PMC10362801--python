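"""Multiplicative coupling-coefficient noise model and SNR.

Measured intensities are modeled as the theoretical reflectances times
Gaussian coupling factors of mean one: one factor per optode (shared by the
two pairs that optode participates in) and one independent "non-cancelable"
(NC) factor per pair.  The variances are apportioned so every single
intensity has the same relative noise σrel:

    I_ds = C_s(1, popt σrel²) · C_d(1, popt σrel²) · C_NC(1, pNC σrel²) · R_ds,
    2·popt + pNC = 1.

The dual ratio cancels the per-optode factors exactly; only the NC factors
survive, so DR noise scales with sqrt(pNC)·σrel while single-distance noise
is σrel·R regardless of pNC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .measurements import IntensityQuartet, dual_ratio

__all__ = [
    "NoiseParams",
    "sample_intensities",
    "dr_noise_stats",
    "dr_noise_delta_method",
    "snr",
]

# Fixed draw order within one experiment's random stream, so a seed is
# reproducible: the four optode factors (sources 1, 2 then detectors A, B),
# then the four NC factors in quartet order (s_I, l_I, s_II, l_II).
_OPTODE_OF_PAIR = {
    # quartet slot -> (source index, detector index) into the optode factors
    "s_I": (0, 2),   # A1
    "l_I": (1, 2),   # A2
    "s_II": (1, 3),  # B2
    "l_II": (0, 3),  # B1
}


@dataclass(frozen=True)
class NoiseParams:
    """Relative noise level and its split into optode and NC fractions.

    ``p_opt`` is derived from the constraint 2·popt + pNC = 1.
    """

    sigma_rel: float = 0.031
    p_nc: float = 0.05

    def __post_init__(self):
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be >= 0")
        if not 0.0 <= self.p_nc <= 1.0:
            raise ValueError(f"p_nc must be in [0, 1], got {self.p_nc}")
        if self.sigma_rel > 0.2:
            raise ValueError(
                "sigma_rel > 0.2 breaks the small-relative-noise Gaussian "
                "model (negative intensities become non-negligible)"
            )

    @property
    def p_opt(self) -> float:
        return (1.0 - self.p_nc) / 2.0


def sample_intensities(
    r_quartet: IntensityQuartet | np.ndarray,
    params: NoiseParams,
    n_draws: int,
    seed: int,
) -> np.ndarray:
    """Draw noisy intensity quartets, shape (n_draws, 4) in quartet order.

    Within one draw the same optode factor multiplies both pairs containing
    that optode; each pair additionally gets its own NC factor.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if isinstance(r_quartet, IntensityQuartet):
        r = r_quartet.as_array()
    else:
        r = np.asarray(r_quartet, dtype=float).reshape(4)
    if np.any(r <= 0):
        raise ValueError("all reflectances must be > 0")
    rng = np.random.default_rng(seed)
    s_opt = np.sqrt(params.p_opt) * params.sigma_rel
    s_nc = np.sqrt(params.p_nc) * params.sigma_rel
    c_opt = rng.normal(1.0, s_opt, size=(n_draws, 4)) if s_opt > 0 else np.ones(
        (n_draws, 4)
    )
    c_nc = rng.normal(1.0, s_nc, size=(n_draws, 4)) if s_nc > 0 else np.ones(
        (n_draws, 4)
    )
    out = np.empty((n_draws, 4))
    for j, slot in enumerate(("s_I", "l_I", "s_II", "l_II")):
        si, di = _OPTODE_OF_PAIR[slot]
        out[:, j] = c_opt[:, si] * c_opt[:, di] * c_nc[:, j] * r[j]
    return out


def dr_noise_stats(
    r_quartet: IntensityQuartet | np.ndarray,
    params: NoiseParams,
    n_draws: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Empirical mean and standard deviation of the sampled dual ratio."""
    draws = sample_intensities(r_quartet, params, n_draws, seed)
    dr = np.sqrt((draws[:, 1] * draws[:, 3]) / (draws[:, 0] * draws[:, 2]))
    return float(dr.mean()), float(dr.std(ddof=1))


def dr_noise_delta_method(
    r_quartet: IntensityQuartet | np.ndarray, params: NoiseParams
) -> float:
    """First-order DR standard deviation, sqrt(pNC)·σrel·DR0.

    Each of the four independent NC factors enters DR at power 1/2, so the
    relative variances add as 4·(1/2)²·pNC·σrel² = pNC·σrel²; the optode
    factors cancel identically and contribute nothing.
    """
    if isinstance(r_quartet, IntensityQuartet):
        dr0 = dual_ratio(r_quartet)
    else:
        dr0 = dual_ratio(np.asarray(r_quartet, dtype=float))
    return float(np.sqrt(params.p_nc) * params.sigma_rel * dr0)


def snr(delta_signal: float, baseline_sd: float) -> float:
    """Signed SNR: background-subtracted signal over baseline noise.

    The sign is kept because a dual-ratio excursion below baseline (SNR
    < −1) is just as detectable as one above it.
    """
    if baseline_sd <= 0:
        raise ValueError("baseline standard deviation must be > 0")
    return delta_signal / baseline_sd
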