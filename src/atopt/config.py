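"""Config file I/O and result export.

A run configuration is a flat YAML/JSON mapping: the model id, the model's
parameter fields by name, the initial composition (``S0`` plus ``R0`` or
``D0``), an optional ``N0`` consistency check, a ``protocol`` mapping, an
optional ``progression`` mapping overriding the rule fractions, and an
optional ``horizon``.  Unknown keys are rejected.

Bundled default configurations (one per model) carry the parameter values
this package ships with; see ``docs/methods.md`` for their provenance.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .engine import DEFAULT_HORIZON, ProgressionRule, SimulationResult, Trajectory
from .experiments import TTPGrid
from .models import LVParams, SCParams, WCParams, TumorState
from .protocols import ProtocolSpec

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "write_config",
    "write_results",
    "bundled_config_path",
    "load_default",
]

_PARAM_TYPES = {"lv": LVParams, "wc": WCParams, "sc": SCParams}
_POP2_KEY = {"lv": "R0", "wc": "R0", "sc": "D0"}


class ConfigError(ValueError):
    """Schema violation in a run configuration, with the offending field."""


@dataclass
class RunConfig:
    """Fully resolved run: model, parameters, protocol, progression rule,
    initial state and horizon."""

    model_id: str
    params: Union[LVParams, WCParams, SCParams]
    protocol: ProtocolSpec
    rule: ProgressionRule
    init: TumorState
    horizon: float = DEFAULT_HORIZON

    @property
    def N0(self) -> float:
        return self.init.total


def _build_params(model_id, data):
    ptype = _PARAM_TYPES[model_id]
    names = [f.name for f in fields(ptype)]
    missing = [n for n in names if n not in data]
    if missing:
        raise ConfigError(f"missing parameter field(s) for model {model_id!r}: {missing}")
    try:
        return ptype(**{n: float(data.pop(n)) for n in names})
    except ValueError as e:
        raise ConfigError(f"invalid parameter value: {e}") from e


def _build_protocol(mapping) -> ProtocolSpec:
    if not isinstance(mapping, dict):
        raise ConfigError("'protocol' must be a mapping")
    allowed = {f.name for f in fields(ProtocolSpec)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown protocol key(s): {sorted(unknown)}")
    if "kind" not in mapping:
        raise ConfigError("protocol requires 'kind'")
    if mapping["kind"] != "CT" and "tau" not in mapping:
        raise ConfigError(f"protocol kind {mapping['kind']!r} requires 'tau'")
    mapping = dict(mapping)
    mapping.setdefault("tau", 30.0)
    try:
        return ProtocolSpec(**mapping)
    except ValueError as e:
        raise ConfigError(f"invalid protocol: {e}") from e


def load_config(path: Union[str, Path]) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    model_id = data.pop("model", None)
    if model_id not in _PARAM_TYPES:
        raise ConfigError(f"'model' must be one of {sorted(_PARAM_TYPES)}, got {model_id!r}")
    params = _build_params(model_id, data)

    pop2_key = _POP2_KEY[model_id]
    if "S0" not in data or pop2_key not in data:
        raise ConfigError(f"model {model_id!r} requires initial composition 'S0' and {pop2_key!r}")
    S0 = float(data.pop("S0"))
    pop2 = float(data.pop(pop2_key))
    init = TumorState(S0, pop2, 0.0)
    if "N0" in data:
        n0 = float(data.pop("N0"))
        if not math.isclose(n0, init.total, rel_tol=1e-9, abs_tol=1e-12):
            raise ConfigError(f"N0={n0} inconsistent with S0 + {pop2_key} = {init.total}")

    protocol = _build_protocol(data.pop("protocol", {"kind": "CT", "tau": 30.0}))

    prog = data.pop("progression", {}) or {}
    if not isinstance(prog, dict):
        raise ConfigError("'progression' must be a mapping")
    unknown = set(prog) - {"growth_frac", "resistant_frac", "cap_frac"}
    if unknown:
        raise ConfigError(f"unknown progression key(s): {sorted(unknown)}")
    if model_id == "wc":
        rule = ProgressionRule.resistant_fraction(
            init.total,
            params.K_R,
            resistant_frac=prog.get("resistant_frac", 0.1),
            cap_frac=prog.get("cap_frac", 1.2),
        )
    else:
        rule = ProgressionRule.total_size(init.total, growth_frac=prog.get("growth_frac", 1.2))

    horizon = float(data.pop("horizon", DEFAULT_HORIZON))
    if data:
        raise ConfigError(f"unknown key(s): {sorted(data)}")
    return RunConfig(model_id, params, protocol, rule, init, horizon)


def write_config(path: Union[str, Path], cfg: RunConfig) -> None:
    """Serialize a RunConfig so that ``load_config`` round-trips it."""
    path = Path(path)
    data: dict = {"model": cfg.model_id}
    data.update(dataclasses.asdict(cfg.params))
    data["S0"] = cfg.init.pop1
    data[_POP2_KEY[cfg.model_id]] = cfg.init.pop2
    data["N0"] = cfg.init.total
    proto = {k: v for k, v in dataclasses.asdict(cfg.protocol).items() if v is not None}
    data["protocol"] = proto
    data["horizon"] = cfg.horizon
    if cfg.model_id == "wc":
        data["progression"] = {
            "resistant_frac": cfg.rule.limit_resistant / cfg.params.K_R,
            "cap_frac": cfg.rule.cap_total / cfg.init.total,
        }
    else:
        data["progression"] = {"growth_frac": cfg.rule.limit_total / cfg.init.total}
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)


def write_results(path: Union[str, Path], obj) -> None:
    """Export a result object: SimulationResult -> JSON, Trajectory or
    TTPGrid -> CSV (long format)."""
    path = Path(path)
    if isinstance(obj, SimulationResult):
        payload = {
            "ttp": None if math.isinf(obj.ttp) else obj.ttp,
            "progressed": obj.progressed,
            "premature": obj.premature,
            "final_state": {
                "t": float(obj.trajectory.times[-1]),
                "pop1": float(obj.trajectory.pop1[-1]),
                "pop2": float(obj.trajectory.pop2[-1]),
            },
            "n_appointments": int(obj.trajectory.appointments.size),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    elif isinstance(obj, Trajectory):
        obj.to_frame().to_csv(path, index=False)
    elif isinstance(obj, TTPGrid):
        obj.to_frame().to_csv(path, index=False)
    elif hasattr(obj, "to_csv"):
        obj.to_csv(path, index=False)
    else:
        raise TypeError(f"cannot export object of type {type(obj).__name__}")


def bundled_config_path(name: str) -> Path:
    """Path to a bundled config, e.g. ``bundled_config_path('lv_default')``."""
    ref = resources.files("atopt").joinpath("configs", f"{name}.yaml")
    p = Path(str(ref))
    if not p.exists():
        raise FileNotFoundError(f"no bundled config named {name!r}")
    return p


def load_default(model_id: str) -> RunConfig:
    """Load the bundled default configuration for a model id."""
    return load_config(bundled_config_path(f"{model_id}_default"))
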