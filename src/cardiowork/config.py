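"""Configuration loading and validation.

A run configuration is a JSON or YAML mapping with optional sections; every
section key must match a known field (unknown keys are rejected with the
offending name), and omitted values fall back to the package defaults::

    T: 0.9                      # heart period, s
    lv:  {E_es: 3.0, lam: 0.027, ...}
    rv:  {...}
    la:  {...}
    ra:  {...}
    valves:
      aortic: {A_max: 2.5, K_vo: 12.0, ...}
      mitral: {...}
    circulation: {E_ao: 3.7, R_sys: 0.92, ...}
    electrical: {nav_delay: 0.03, ra_delay: 0.01, la_delay: 0.03,
                 av_udp: 0.09}
    solver: {dt: 0.00025, sample_dt: 0.001, xi_threshold: 0.05}
    ea: {population: 50, generations: 60, ...}
    morris: {r: 10, range_fraction: 0.3, levels: 4}
    seed: 1
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .chambers import AtriumParams, VentricleParams
from .circulation import CirculationParams
from .electrical import standard_network
from .identification import EAConfig
from .parameters import ParameterSet
from .simulator import SolverConfig
from .valves import ValveParams

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Human-readable configuration schema violation."""


@dataclass
class MorrisSettings:
    r: int = 10
    range_fraction: float = 0.30
    levels: int = 4
    operating_ava: float = 1.0


@dataclass
class RunConfig:
    """Fully-resolved run configuration."""

    parameters: ParameterSet = field(default_factory=ParameterSet)
    solver: SolverConfig = field(default_factory=SolverConfig)
    ea: EAConfig = field(default_factory=EAConfig)
    morris: MorrisSettings = field(default_factory=MorrisSettings)
    seed: int | None = None
    electrical_overrides: dict = field(default_factory=dict)


def _build(cls, section: dict, where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(
            f"unknown key {sorted(unknown)[0]!r} in section {where!r} "
            f"(known keys: {sorted(known)})")
    try:
        return cls(**section)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid section {where!r}: {err}") from err


_ELECTRICAL_KEYS = {"nav_delay", "ra_delay", "la_delay", "av_udp"}
_TOP_KEYS = {"T", "lv", "rv", "la", "ra", "valves", "circulation",
             "electrical", "solver", "ea", "morris", "seed"}


def load_config(path) -> RunConfig:
    """Load and validate a JSON/YAML run configuration.

    Defaults are filled for every omitted value; unknown keys raise a
    :class:`ConfigError` naming the offending key.
    """
    path = Path(path)
    text = path.read_text()
    raw = (json.loads(text) if path.suffix == ".json"
           else yaml.safe_load(text)) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown key {sorted(unknown)[0]!r} at top level")

    kwargs: dict = {}
    if "T" in raw:
        kwargs["T"] = float(raw["T"])
    for name, cls in (("lv", VentricleParams), ("rv", VentricleParams),
                      ("la", AtriumParams), ("ra", AtriumParams)):
        if name in raw:
            defaults = dataclasses.asdict(getattr(ParameterSet(), name))
            defaults.update(raw[name] or {})
            kwargs[name] = _build(cls, defaults, name)
    if "valves" in raw:
        valves = {n: dataclasses.replace(v)
                  for n, v in ParameterSet().valves.items()}
        for vname, sec in (raw["valves"] or {}).items():
            if vname not in valves:
                raise ConfigError(f"unknown valve {vname!r}")
            defaults = dataclasses.asdict(valves[vname])
            defaults.update(sec or {})
            valves[vname] = _build(ValveParams, defaults, f"valves.{vname}")
        kwargs["valves"] = valves
    if "circulation" in raw:
        defaults = dataclasses.asdict(CirculationParams())
        defaults.update(raw["circulation"] or {})
        kwargs["circ"] = _build(CirculationParams, defaults, "circulation")

    electrical_overrides = {}
    if "electrical" in raw:
        sec = raw["electrical"] or {}
        unknown = set(sec) - _ELECTRICAL_KEYS
        if unknown:
            raise ConfigError(f"unknown key {sorted(unknown)[0]!r} in "
                              "section 'electrical'")
        electrical_overrides = {k: float(v) for k, v in sec.items()}

    ps = ParameterSet(**kwargs)
    if electrical_overrides:
        ps.electrical = standard_network(ps.T, **electrical_overrides)

    solver = _build(SolverConfig, raw.get("solver") or {}, "solver")
    ea = _build(EAConfig, raw.get("ea") or {}, "ea")
    morris = _build(MorrisSettings, raw.get("morris") or {}, "morris")
    seed = raw.get("seed")
    return RunConfig(parameters=ps, solver=solver, ea=ea, morris=morris,
                     seed=None if seed is None else int(seed),
                     electrical_overrides=electrical_overrides)


def dump_config(cfg: RunConfig, path) -> None:
    """Write the fully-resolved configuration next to run outputs
    (provenance); the dump reloads to an identical configuration."""
    ps = cfg.parameters
    out = {
        "T": ps.T,
        "lv": dataclasses.asdict(ps.lv),
        "rv": dataclasses.asdict(ps.rv),
        "la": dataclasses.asdict(ps.la),
        "ra": dataclasses.asdict(ps.ra),
        "valves": {n: dataclasses.asdict(v) for n, v in ps.valves.items()},
        "circulation": dataclasses.asdict(ps.circ),
        "solver": dataclasses.asdict(cfg.solver),
        "ea": {**dataclasses.asdict(cfg.ea),
               "mutation": list(cfg.ea.mutation)},
        "morris": dataclasses.asdict(cfg.morris),
    }
    if cfg.electrical_overrides:
        out["electrical"] = cfg.electrical_overrides
    if cfg.seed is not None:
        out["seed"] = cfg.seed
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(out, indent=1))
    else:
        path.write_text(yaml.safe_dump(out, sort_keys=False))
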