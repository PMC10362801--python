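"""Run configuration: YAML-backed, validated, defaulting to the standard
study conditions (810 nm tissue-like medium, symmetric four-optode layout,
phantom-calibrated fluorescence coefficients and noise levels).

All physical quantities carry explicit unit suffixes in their key names.
Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .calibrate import ConversionConstant
from .fluorescence import AFModel, TargetModel
from .measurements import MeasurementGeometry, default_geometry
from .noise import NoiseParams
from .transport import OpticalMedium, OptodeSpec, TimeGates

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """The configuration file violates the schema."""


_DEFAULTS: dict = {
    "medium": {
        "mu_a_mm1": 0.002,
        "mu_s_mm1": 7.0,
        "g": 0.9,
        "n_in": 1.37,
        "n_out": 1.0,
        "extent_mm": [30.0, 30.0, 15.0],
        "voxel_mm": 0.25,
    },
    "optodes": {
        "na": 0.5,
        "sources_mm": {"1": [-0.5, 0.0], "2": [0.5, 0.0]},
        "detectors_mm": {"A": [-3.5, 0.0], "B": [3.5, 0.0]},
    },
    "transport": {
        "n_photons": 4_000_000,
        "seed": 7,
        "n_gates": 10,
        "t_end_ns": 10.0,
    },
    "af": {
        "kind": "surface_weighted",
        "coefficient_mm1": 228e-9,
        "half_depth_mm": 0.1,
    },
    "target": {
        "coefficient_mm1": 43.3e-6,
        "depth_mm": 1.5,
        "velocity_mm_s": 25.0,
    },
    "noise": {"sigma_rel": 0.031, "p_nc": 0.05, "p_opt": None},
    "source_power_mW": 75.0,
    "conversion_W_mm2_per_nA": 271e-15,
}


@dataclass
class RunConfig:
    """Validated configuration for the simulation workflows."""

    raw: dict

    @property
    def medium(self) -> OpticalMedium:
        m = self.raw["medium"]
        return OpticalMedium(
            mu_a=m["mu_a_mm1"],
            mu_s=m["mu_s_mm1"],
            g=m["g"],
            n_in=m["n_in"],
            n_out=m["n_out"],
            extent=tuple(m["extent_mm"]),
            voxel=m["voxel_mm"],
        )

    @property
    def geometry(self) -> MeasurementGeometry:
        o = self.raw["optodes"]
        sources = {
            name: OptodeSpec((p[0], p[1], 0.0), role="source", beam="pencil")
            for name, p in o["sources_mm"].items()
        }
        detectors = {
            name: OptodeSpec(
                (p[0], p[1], 0.0), role="detector", beam="cone", na=o["na"]
            )
            for name, p in o["detectors_mm"].items()
        }
        return MeasurementGeometry(sources=sources, detectors=detectors)

    @property
    def gates(self) -> TimeGates:
        t = self.raw["transport"]
        return TimeGates(t["n_gates"], t["t_end_ns"])

    @property
    def n_photons(self) -> int:
        return int(self.raw["transport"]["n_photons"])

    @property
    def seed(self) -> int:
        return int(self.raw["transport"]["seed"])

    @property
    def af(self) -> AFModel:
        a = self.raw["af"]
        return AFModel(
            kind=a["kind"],
            coefficient=a["coefficient_mm1"],
            half_depth=a["half_depth_mm"],
        )

    @property
    def target(self) -> TargetModel:
        t = self.raw["target"]
        return TargetModel(
            coefficient=t["coefficient_mm1"],
            position=(0.0, 0.0, t["depth_mm"]),
            velocity=t["velocity_mm_s"],
        )

    @property
    def noise(self) -> NoiseParams:
        n = self.raw["noise"]
        return NoiseParams(sigma_rel=n["sigma_rel"], p_nc=n["p_nc"])

    @property
    def p_src(self) -> float:
        return float(self.raw["source_power_mW"])

    @property
    def conversion(self) -> ConversionConstant:
        return ConversionConstant(factor=self.raw["conversion_W_mm2_per_nA"])

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, for provenance."""
        blob = json.dumps(self.raw, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    unknown = [k for k in user if k not in defaults]
    if unknown:
        raise ConfigError(
            f"unknown configuration key(s) {unknown} at {path or 'top level'}"
        )
    for k, dv in defaults.items():
        if k not in user:
            out[k] = dv
        elif isinstance(dv, dict) and k not in ("sources_mm", "detectors_mm"):
            if not isinstance(user[k], dict):
                raise ConfigError(f"{path}{k} must be a mapping")
            out[k] = _merge(dv, user[k], f"{path}{k}.")
        else:
            out[k] = user[k]
    return out


def _validate(raw: dict) -> None:
    noise = raw["noise"]
    p_opt = noise.pop("p_opt", None)
    if p_opt is not None:
        if abs(2 * p_opt + noise["p_nc"] - 1.0) > 1e-9:
            raise ConfigError(
                f"noise fractions must satisfy 2*p_opt + p_nc = 1; got "
                f"2*{p_opt} + {noise['p_nc']} = {2 * p_opt + noise['p_nc']}"
            )
    try:
        cfg = RunConfig(raw)
        cfg.medium
        cfg.geometry
        cfg.gates
        cfg.af
        cfg.target
        cfg.noise
        cfg.conversion
    except ConfigError:
        raise
    except (ValueError, KeyError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; missing keys take the defaults.

    ``path=None`` (or an empty file) yields the full default
    configuration.  ``overrides`` is an optional nested dict applied on
    top of the file's content (used by CLI flags).
    """
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError("config file must contain a mapping")
            user = loaded
    raw = _merge(copy.deepcopy(_DEFAULTS), user)
    for key, sub in (overrides or {}).items():
        if isinstance(sub, dict):
            raw[key] = {**raw[key], **sub}
        else:
            raw[key] = sub
    _validate(raw)
    return RunConfig(raw)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.raw, fh, sort_keys=True)
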