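"""Single-distance, single-ratio and dual-ratio measurement algebra.

SD is the raw intensity of one source-detector pair; SR is the ratio of a
long-distance to a short-distance intensity; DR is the geometric mean of
two SRs whose optodes are arranged so that every optode appears once in a
short-ρ pair and once in a long-ρ pair.  That symmetry is what lets DR
cancel every multiplicative per-optode coupling factor exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .transport import OptodeSpec

__all__ = [
    "MeasurementGeometry",
    "IntensityQuartet",
    "PAIR_ORDER",
    "delta_sd",
    "single_ratio",
    "delta_sr",
    "dual_ratio",
    "delta_dr",
    "validate_dr_layout",
    "default_geometry",
]

# Canonical quartet ordering: (short,I), (long,I), (short,II), (long,II).
PAIR_ORDER = ("s_I", "l_I", "s_II", "l_II")


@dataclass(frozen=True)
class MeasurementGeometry:
    """Two sources and two detectors on the surface, with pair distances."""

    sources: dict[str, OptodeSpec]
    detectors: dict[str, OptodeSpec]

    def __post_init__(self):
        for name, o in self.sources.items():
            if o.role != "source":
                raise ValueError(f"optode {name} is not a source")
        for name, o in self.detectors.items():
            if o.role != "detector":
                raise ValueError(f"optode {name} is not a detector")

    def rho(self, det: str, src: str) -> float:
        a = self.detectors[det].position
        b = self.sources[src].position
        return math.dist(a[:2], b[:2])

    def pairs(self) -> dict[str, float]:
        """All detector-source combinations with their ρ in mm."""
        return {
            f"{d}{s}": self.rho(d, s)
            for d in self.detectors
            for s in self.sources
        }


def default_geometry(na: float = 0.5) -> MeasurementGeometry:
    """The standard symmetric layout: detectors at ±3.5 mm, sources at ±0.5 mm.

    Gives ρ(A1) = ρ(B2) = 3 mm (short) and ρ(A2) = ρ(B1) = 4 mm (long).
    """
    return MeasurementGeometry(
        sources={
            "1": OptodeSpec((-0.5, 0.0, 0.0), role="source", beam="pencil"),
            "2": OptodeSpec((0.5, 0.0, 0.0), role="source", beam="pencil"),
        },
        detectors={
            "A": OptodeSpec((-3.5, 0.0, 0.0), role="detector", beam="cone", na=na),
            "B": OptodeSpec((3.5, 0.0, 0.0), role="detector", beam="cone", na=na),
        },
    )


@dataclass(frozen=True)
class IntensityQuartet:
    """Intensities for the four DR pairs, ordered (s,I), (l,I), (s,II), (l,II)."""

    s_I: float
    l_I: float
    s_II: float
    l_II: float

    def as_array(self) -> np.ndarray:
        return np.array([self.s_I, self.l_I, self.s_II, self.l_II])

    def __post_init__(self):
        if min(self.s_I, self.l_I, self.s_II, self.l_II) <= 0:
            raise ValueError("all quartet intensities must be > 0")


def delta_sd(i_t: float, i_0: float) -> float:
    """Background-subtracted single-distance intensity, ΔSD = I(t) − I0."""
    return i_t - i_0


def single_ratio(i_long: float, i_short: float) -> float:
    """SR = I_long / I_short."""
    if i_short <= 0:
        raise ZeroDivisionError("short-distance intensity must be > 0")
    return i_long / i_short


def delta_sr(i_long: float, i_short: float, i_long_0: float, i_short_0: float) -> float:
    """ΔSR(t) = SR(t) − SR0."""
    return single_ratio(i_long, i_short) - single_ratio(i_long_0, i_short_0)


def dual_ratio(q: IntensityQuartet | np.ndarray) -> float:
    """DR = sqrt( (I_l,I · I_l,II) / (I_s,I · I_s,II) )."""
    if isinstance(q, IntensityQuartet):
        s1, l1, s2, l2 = q.s_I, q.l_I, q.s_II, q.l_II
    else:
        s1, l1, s2, l2 = np.asarray(q, dtype=float).reshape(4)
    if min(s1, l1, s2, l2) <= 0:
        raise ZeroDivisionError("dual ratio needs four positive intensities")
    return math.sqrt((l1 * l2) / (s1 * s2))


def delta_dr(q_t: IntensityQuartet, q_0: IntensityQuartet) -> float:
    """ΔDR(t) = DR(t) − DR0."""
    return dual_ratio(q_t) - dual_ratio(q_0)


def validate_dr_layout(
    geom: MeasurementGeometry, tol: float = 1e-6
) -> tuple[bool, dict[str, str], str]:
    """Check the DR symmetry requirement and assign the four quartet slots.

    The requirement: the two short-ρ pairs share no optode, every optode
    contributes once at short and once at long ρ, the two short ρs match
    each other (and likewise the long ones) within ``tol`` mm, and short
    differs from long.  Returns ``(valid, assignment, diagnostic)`` where
    ``assignment`` maps the quartet slots to pair names like ``"A1"``.
    """
    if len(geom.sources) != 2 or len(geom.detectors) != 2:
        raise ValueError("DR needs exactly two sources and two detectors")
    (d1, d2) = sorted(geom.detectors)
    (s1, s2) = sorted(geom.sources)
    # Two candidate pairings of the four SD combinations into short/long sets:
    # SR_I on detector d1, SR_II on detector d2, short pair either (d1 s1, d2 s2)
    # or (d1 s2, d2 s1).
    for short_srcs in ((s1, s2), (s2, s1)):
        sa, sb = short_srcs
        la, lb = (s2, s1) if sa == s1 else (s1, s2)
        rho_s1, rho_s2 = geom.rho(d1, sa), geom.rho(d2, sb)
        rho_l1, rho_l2 = geom.rho(d1, la), geom.rho(d2, lb)
        if abs(rho_s1 - rho_s2) > tol or abs(rho_l1 - rho_l2) > tol:
            continue
        if rho_l1 <= rho_s1 + tol:
            if abs(rho_l1 - rho_s1) <= tol:
                return (
                    False,
                    {},
                    "degenerate layout: short and long distances coincide",
                )
            continue  # this pairing has long < short; try the other
        assignment = {
            "s_I": f"{d1}{sa}",
            "l_I": f"{d1}{la}",
            "s_II": f"{d2}{sb}",
            "l_II": f"{d2}{lb}",
        }
        return True, assignment, ""
    return (
        False,
        {},
        "layout breaks DR symmetry: no pairing gives matched short and "
        "long distances",
    )
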