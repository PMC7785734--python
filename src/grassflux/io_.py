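"""Tidy CSV interchange, configuration loading and run manifests.

Every table crosses stage boundaries as tidy CSV with an explicit unit
column — units are data, never implied by file position. The flux
variable column encodes component and management class as
``component/management`` so a FluxTable round-trips through one file.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from grassflux.balance import GasConstants
from grassflux.rf import IRFParams
from grassflux.synthetic import RegionParams, ScenarioConfig
from grassflux.tables import ACTIVITY_COLUMNS, make_flux_table
from grassflux.tier import EmissionFactorSet
from grassflux.uncertainty import EmissionConstraint, UncertaintySpec

__all__ = [
    "write_flux_table", "read_flux_table",
    "write_activity_table", "read_activity_table",
    "write_landcover_table", "read_landcover_table",
    "load_config", "ConfigError", "config_objects",
    "RunManifest", "sha256_digest",
]


def write_flux_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["variable"] = out["component"] + "/" + out["management"]
    out[["region", "year", "variable", "value", "unit"]].to_csv(path, index=False)


def read_flux_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    parts = df["variable"].str.split("/", expand=True)
    df["component"], df["management"] = parts[0], parts[1]
    return make_flux_table(df.to_dict("records"))


def write_activity_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_activity_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("region", "year", *ACTIVITY_COLUMNS) if c not in df.columns]
    if missing:
        raise ValueError(f"activity file missing column(s): {missing}")
    return df


def write_landcover_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_landcover_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


class ConfigError(ValueError):
    """Configuration file violates the schema; message carries the key path."""


# schema: nested dict of key -> default (None = required-free leaf accepting
# any scalar); dicts marked OPEN accept arbitrary sub-keys (region names).
_OPEN = "__open__"

_SCHEMA: dict = {
    "scenario": {
        "regions": None,
        "start_year": 1750,
        "end_year": 2012,
        "seed": 0,
        "region_params": {_OPEN: {f: None for f in RegionParams.__dataclass_fields__}},
    },
    "constants": {"gwp_ch4": 34.0, "gwp_n2o": 267.0, "horizon": 100.0},
    "factors": {f: None for f in EmissionFactorSet.__dataclass_fields__ if f != "uncertainty"},
    "rf": {
        "steps_per_year": 4,
        "co2_rf_mode": "linear",
        "with_feedback": False,
    },
    "attribution": {"epsilon": 0.01, "year": 2012},
    "montecarlo": {
        "n_samples": 500,
        "co2_rel_sd": 0.46,
        "luc_rel_sd": 0.31,
        "seed": 42,
        "constraints": None,  # list of {gas, year, reference, sd}
    },
}


def _validate(user: dict, schema: dict, path: str = "") -> dict:
    if not isinstance(user, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping")
    out = {}
    open_schema = schema.get(_OPEN)
    for key, value in user.items():
        here = f"{path}.{key}" if path else key
        if key in schema:
            sub = schema[key]
        elif open_schema is not None:
            sub = open_schema
        else:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(sub, dict):
            out[key] = _validate(value if value is not None else {}, sub, here)
        else:
            out[key] = value
    for key, default in schema.items():
        if key == _OPEN or key in out:
            continue
        if isinstance(default, dict):
            out[key] = _validate({}, default, f"{path}.{key}" if path else key)
        elif default is not None:
            out[key] = default
    return out


def load_config(path) -> dict:
    """Load and schema-validate a YAML configuration file.

    Defaults are injected for absent keys (e.g. ``constants.gwp_ch4 =
    34``); unknown keys are rejected with their full key path.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return _validate(raw, _SCHEMA)


def config_objects(cfg: dict):
    """Build the typed configuration objects from a validated config dict."""
    scen = cfg.get("scenario", {})
    region_params = {
        region: RegionParams(**{k: v for k, v in params.items() if v is not None})
        for region, params in scen.get("region_params", {}).items()
    }
    kwargs = {}
    if scen.get("regions") is not None:
        kwargs["regions"] = tuple(scen["regions"])
    scenario = ScenarioConfig(
        start_year=scen.get("start_year", 1750), end_year=scen.get("end_year", 2012),
        seed=scen.get("seed", 0), region_params=region_params, **kwargs,
    )
    constants = GasConstants(
        gwp_ch4=cfg["constants"]["gwp_ch4"], gwp_n2o=cfg["constants"]["gwp_n2o"],
        horizon=cfg["constants"]["horizon"],
    )
    factors = EmissionFactorSet(
        **{k: v for k, v in cfg.get("factors", {}).items() if v is not None})
    rf_cfg = cfg.get("rf", {})
    params = IRFParams(
        steps_per_year=rf_cfg.get("steps_per_year", 4),
        co2_rf_mode=rf_cfg.get("co2_rf_mode", "linear"),
    )
    mc = cfg.get("montecarlo", {})
    constraints = tuple(
        EmissionConstraint(**c) for c in (mc.get("constraints") or [])
    )
    spec = UncertaintySpec(
        n_samples=mc.get("n_samples", 500), co2_rel_sd=mc.get("co2_rel_sd", 0.46),
        luc_rel_sd=mc.get("luc_rel_sd", 0.31), constraints=constraints,
    )
    return scenario, constants, factors, params, spec


def sha256_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every pipeline run."""

    config: dict
    seeds: dict[str, int]
    version: str
    started: float = field(default_factory=time.time)
    files: dict[str, str] = field(default_factory=dict)  # name -> sha256

    def record(self, name: str, path) -> None:
        self.files[name] = sha256_digest(path)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @staticmethod
    def read(path) -> "RunManifest":
        with open(path) as fh:
            return RunManifest(**json.load(fh))

    def verify(self, directory) -> list[str]:
        """Names of recorded files whose digests no longer match."""
        from pathlib import Path

        bad = []
        for name, digest in self.files.items():
            p = Path(directory) / name
            if not p.exists() or sha256_digest(p) != digest:
                bad.append(name)
        return bad
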