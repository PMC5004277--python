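"""Structured run configuration: YAML blocks mirroring the model symbols.

A run configuration collects the blocks

* ``composition`` -- M_c, M_h, M_l, M_o (%), rho_c, rho_h, rho_l, rho_o (g/cm^3)
* ``particle``    -- R (cm), V_p, V_pa (cm^3/g)
* ``batch``       -- m (g), V_L (mL), C_0 (mg/mL)
* ``langmuir``    -- q_m (mg/g), K_a (mL/mg)                       [optional]
* ``transport``   -- K_L (cm/min), D_p, D_s (cm^2/min)             [optional]
* ``solver``      -- N, rtol, atol                                 [optional]
* ``synth``       -- sd_rel, sd_abs, seed                          [optional]

Unknown keys anywhere are rejected, loaded values are echoed to the log,
and derived particle properties are computed on load so unit or invariant
problems surface immediately.  Reference configurations for the two
corn-stover preparations (sieve-ground, SGCS, and ultrafine-ground, UGCS)
ship with the package.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigError
from .fps_solver import DEFAULT_ATOL, DEFAULT_N, DEFAULT_RTOL, TransportParams
from .isotherm import LangmuirParams
from .properties import ParticleSystem, SubstrateComposition
from .synthetic_data import NoiseModel

__all__ = ["SolverSettings", "RunConfig", "load_config", "dump_config", "builtin_config"]

log = logging.getLogger("cellsorb")

_BLOCK_KEYS = {
    "composition": {"M_c", "M_h", "M_l", "M_o", "rho_c", "rho_h", "rho_l", "rho_o"},
    "particle": {"R", "V_p", "V_pa"},
    "batch": {"m", "V_L", "C_0"},
    "langmuir": {"q_m", "K_a"},
    "transport": {"K_L", "D_p", "D_s"},
    "solver": {"N", "rtol", "atol"},
    "synth": {"sd_rel", "sd_abs", "seed"},
}
_REQUIRED_BLOCKS = ("composition", "particle", "batch")


@dataclass(frozen=True)
class SolverSettings:
    N: int = DEFAULT_N
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL


@dataclass(frozen=True)
class RunConfig:
    system: ParticleSystem
    langmuir: LangmuirParams | None = None
    transport: TransportParams | None = None
    solver: SolverSettings = field(default_factory=SolverSettings)
    noise: NoiseModel = field(default_factory=NoiseModel)
    source: str = "<memory>"


def _check_block(name: str, block: dict, required: bool = True) -> dict:
    if not isinstance(block, dict):
        raise ConfigError(f"block {name!r} must be a mapping")
    allowed = _BLOCK_KEYS[name]
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in block {name!r}; "
                          f"allowed: {sorted(allowed)}")
    if required:
        missing = allowed - set(block)
        if missing:
            raise ConfigError(f"missing key(s) {sorted(missing)} in block {name!r}")
    for k, v in block.items():
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise ConfigError(f"{name}.{k} must be numeric, got {v!r}")
    return dict(block)


def _build(raw: dict, source: str) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping of blocks")
    unknown = set(raw) - set(_BLOCK_KEYS)
    if unknown:
        raise ConfigError(f"unknown block(s) {sorted(unknown)}; "
                          f"allowed: {sorted(_BLOCK_KEYS)}")
    for name in _REQUIRED_BLOCKS:
        if name not in raw:
            raise ConfigError(f"missing required block {name!r}")

    comp = SubstrateComposition(**_check_block("composition", raw["composition"]))
    particle = _check_block("particle", raw["particle"])
    batch = _check_block("batch", raw["batch"])
    try:
        system = ParticleSystem(R=particle["R"], V_p=particle["V_p"],
                                V_pa=particle["V_pa"], m=batch["m"],
                                V_L=batch["V_L"], C_0=batch["C_0"],
                                composition=comp)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    langmuir = transport = None
    if "langmuir" in raw:
        langmuir = LangmuirParams(**_check_block("langmuir", raw["langmuir"]))
    if "transport" in raw:
        transport = TransportParams(**_check_block("transport", raw["transport"]))
    solver = SolverSettings(**_check_block("solver", raw.get("solver", {}), required=False))
    noise = NoiseModel(**_check_block("synth", raw.get("synth", {}), required=False))

    cfg = RunConfig(system=system, langmuir=langmuir, transport=transport,
                    solver=solver, noise=noise, source=source)
    der = system.derived()
    log.info("loaded config %s: rho_s=%.4f rho_a=%.4f eps=%.5f phi=%.4f A=%.3f cm^2",
             source, der.rho_s, der.rho_a, der.eps, der.phi, der.A)
    for name in _BLOCK_KEYS:
        if name in raw:
            log.info("  %s: %s", name, raw[name])
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise ConfigError(f"configuration file {path} does not exist") from None
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return _build(raw, source=str(path))


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Serialise a RunConfig back to YAML (round-trips through load_config)."""
    comp = asdict(cfg.system.composition)
    comp.pop("sum_tolerance", None)
    raw: dict = {
        "composition": comp,
        "particle": {"R": cfg.system.R, "V_p": cfg.system.V_p, "V_pa": cfg.system.V_pa},
        "batch": {"m": cfg.system.m, "V_L": cfg.system.V_L, "C_0": cfg.system.C_0},
        "solver": asdict(cfg.solver),
        "synth": asdict(cfg.noise),
    }
    if cfg.langmuir is not None:
        raw["langmuir"] = {"q_m": cfg.langmuir.q_m, "K_a": cfg.langmuir.K_a}
    if cfg.transport is not None:
        raw["transport"] = asdict(cfg.transport)
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def builtin_config(name: str) -> RunConfig:
    """Load one of the packaged reference configurations ('sgcs' or 'ugcs')."""
    ref = resources.files("cellsorb.data") / f"{name.lower()}.yaml"
    if not ref.is_file():
        raise ConfigError(f"no builtin configuration named {name!r}")
    raw = yaml.safe_load(ref.read_text())
    return _build(raw, source=f"builtin:{name.lower()}")
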