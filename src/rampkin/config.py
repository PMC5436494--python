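"""Campaign configuration: YAML loading, validation, defaults, hashing.

A config file mirrors the rig: reactor geometry, thermal expansion,
fluid properties, the ramp program, factorial levels, feed stocks, the
kinetic scheme, the noise model, fit settings and dispersion settings.
Unknown keys are rejected so typos fail loudly, and every output carries
a short hash of the fully resolved config for provenance.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass

import yaml

from .dispersion import FluidProperties
from .errors import ConfigError
from .fitting import FitSpec
from .flow import CampaignDesign, ReactorGeometry, ThermalExpansionModel
from .network import KineticScheme, snar_scheme
from .rig import NoiseModel

DEFAULTS: dict = {
    "reactor": {"volume_mL": 5.0, "d_t_mm": 0.79, "d_c_mm": None},
    "thermal": {"alpha_v_per_K": 1.1e-3, "T0_C": 25.0},
    "fluid": {"rho_kg_m3": 789.0, "mu_Pa_s": 1.07e-3, "D_m_m2_s": 0.8e-9},
    "ramp": {
        "Q_start_mL_min": 10.0,
        "Q_end_mL_min": 1.5,
        "alpha_mL_min2": 0.836,
        "alpha_mL_s2": None,  # alternative unit; converted if given
        "injection_interval_min": 2.0,
        "hold_min": 2.0,
        "first_injection_at_onset": True,
    },
    "levels": {
        "equivalents": [1.5, 4.0, 7.0],
        "temperatures_C": [30.0, 60.0, 90.0, 120.0],
    },
    "stocks": {"C1_M": 0.4, "C2_M": 2.0, "substrate_fraction": 0.25},
    "scheme": {"name": "snar-default", "nucleophile_stoich_factor": 1},
    "noise": {"relative_sd": 0.02, "absolute_sd_M": 1e-4, "enabled": False},
    "fit": {
        "T_ref_C": 90.0,
        "protocol": "two-stage",  # "two-stage" | "global"
        "vary_Ea": True,
        "weighting": "absolute",
        "init_k_ref": 0.1,
        "init_Ea_kJ_mol": 50.0,
    },
    "dispersion": {"kappa": 0.15, "mask_threshold": 0.05},
    "seed": 0,
}

_NUMERIC_POSITIVE = {
    ("reactor", "volume_mL"),
    ("reactor", "d_t_mm"),
    ("fluid", "rho_kg_m3"),
    ("fluid", "mu_Pa_s"),
    ("fluid", "D_m_m2_s"),
    ("ramp", "Q_start_mL_min"),
    ("ramp", "injection_interval_min"),
    ("stocks", "C1_M"),
    ("stocks", "C2_M"),
}


@dataclass
class CampaignConfig:
    """Fully validated campaign configuration."""

    raw: dict
    config_hash: str

    # -- constructed objects -------------------------------------------------
    @property
    def geometry(self) -> ReactorGeometry:
        r = self.raw["reactor"]
        d_c = r["d_c_mm"]
        return ReactorGeometry(
            volume_mL=r["volume_mL"],
            d_t=r["d_t_mm"] * 1e-3,
            d_c=None if d_c is None else d_c * 1e-3,
        )

    @property
    def thermal(self) -> ThermalExpansionModel:
        t = self.raw["thermal"]
        return ThermalExpansionModel(alpha_v=t["alpha_v_per_K"], T0=t["T0_C"] + 273.15)

    @property
    def fluid(self) -> FluidProperties:
        f = self.raw["fluid"]
        return FluidProperties(rho=f["rho_kg_m3"], mu=f["mu_Pa_s"], D_m=f["D_m_m2_s"])

    @property
    def design(self) -> CampaignDesign:
        r, lv, st = self.raw["ramp"], self.raw["levels"], self.raw["stocks"]
        return CampaignDesign(
            geometry=self.geometry,
            thermal=self.thermal,
            Q_start=r["Q_start_mL_min"],
            Q_end=r["Q_end_mL_min"],
            alpha=r["alpha_mL_min2"],
            injection_interval_min=r["injection_interval_min"],
            hold_min=r["hold_min"],
            equivalents_levels=tuple(lv["equivalents"]),
            temperatures_C=tuple(lv["temperatures_C"]),
            C1_stock=st["C1_M"],
            C2_stock=st["C2_M"],
            substrate_fraction=st["substrate_fraction"],
            first_injection_at_onset=r["first_injection_at_onset"],
        )

    @property
    def scheme(self) -> KineticScheme:
        s = self.raw["scheme"]
        if s["name"] != "snar-default":
            raise ConfigError(
                f"unknown scheme {s['name']!r}; 'snar-default' is the built-in"
            )
        return snar_scheme(s["nucleophile_stoich_factor"])

    @property
    def noise(self) -> NoiseModel | None:
        n = self.raw["noise"]
        if not n["enabled"]:
            return None
        return NoiseModel(n["relative_sd"], n["absolute_sd_M"], seed=self.seed)

    @property
    def fit_spec(self) -> FitSpec:
        f = self.raw["fit"]
        return FitSpec(
            T_ref=f["T_ref_C"] + 273.15,
            vary_Ea=f["vary_Ea"],
            weighting=f["weighting"],
            init_k_ref=f["init_k_ref"],
            init_Ea=f["init_Ea_kJ_mol"] * 1000.0,
        )

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def serialized(self) -> str:
        return yaml.safe_dump(self.raw, sort_keys=True)


def _merge_validate(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown config key {here!r}")
        if isinstance(defaults[key], dict) and defaults[key]:
            if not isinstance(val, dict):
                raise ConfigError(f"config key {here!r} must be a mapping")
            out[key] = _merge_validate(defaults[key], val, here)
        else:
            out[key] = val
    return out


def validate_config(raw: dict) -> dict:
    cfg = _merge_validate(DEFAULTS, raw)
    # unit alternative: ramp deceleration given per second
    if cfg["ramp"]["alpha_mL_s2"] is not None:
        cfg["ramp"]["alpha_mL_min2"] = cfg["ramp"]["alpha_mL_s2"] * 3600.0
        cfg["ramp"]["alpha_mL_s2"] = None
    for section, key in _NUMERIC_POSITIVE:
        v = cfg[section][key]
        if not isinstance(v, (int, float)) or v <= 0:
            raise ConfigError(f"config key {section}.{key} must be positive, got {v!r}")
    if cfg["ramp"]["alpha_mL_min2"] < 0:
        raise ConfigError("ramp.alpha_mL_min2 must be non-negative")
    if cfg["noise"]["relative_sd"] < 0 or cfg["noise"]["absolute_sd_M"] < 0:
        raise ConfigError("noise standard deviations must be non-negative")
    if not 0 < cfg["stocks"]["substrate_fraction"] < 1:
        raise ConfigError("stocks.substrate_fraction must be in (0, 1)")
    if not cfg["levels"]["equivalents"] or not cfg["levels"]["temperatures_C"]:
        raise ConfigError("levels.equivalents and levels.temperatures_C must be non-empty")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def load_config(path: str | None = None, overrides: dict | None = None) -> CampaignConfig:
    """Load and validate a YAML config; ``path=None`` gives pure defaults.

    ``overrides`` (nested dict) is applied after the file, useful for
    CLI flags such as ``--seed``.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        raw = loaded
    if overrides:
        raw = _merge_validate(validate_config(raw), overrides)
    cfg = validate_config(raw)
    return CampaignConfig(raw=cfg, config_hash=config_hash(cfg))
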