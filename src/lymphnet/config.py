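"""Structured run configuration: YAML sections over the baseline defaults.

Config files are flat key-value sections; every key is optional (an empty
file is the full baseline configuration) and unknown keys are rejected with
their path named. Pressures in config files are in cmH2O, the physiological
reporting unit; everything is converted to cgs internally and the resolved
values are echoed to the log.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .experiments import BaseCase
from .model_core import PhysicalParams
from .solver import BoundaryConditions, SolverSettings

__all__ = ["RunConfig", "load_config"]

log = logging.getLogger("lymphnet")

_PHYSICAL_KEYS = set(PhysicalParams._STORED)
_NETWORK_KEYS = {"n_generations", "nv"}
_TIMING_KEYS = {"dtv", "dtg"}
_BOUNDARY_KEYS = {"pa_cmH2O", "pb_cmH2O", "pe_cmH2O"}
_SOLVER_KEYS = {f.name for f in dataclasses.fields(SolverSettings)}
_OUTPUT_KEYS = {"out_dir", "write_series"}
_SCHEMA = {
    "physical": _PHYSICAL_KEYS, "network": _NETWORK_KEYS,
    "timing": _TIMING_KEYS, "boundary": _BOUNDARY_KEYS,
    "solver": _SOLVER_KEYS, "output": _OUTPUT_KEYS,
}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration; defaults are the baseline conditions."""

    physical: PhysicalParams = field(default_factory=PhysicalParams)
    n_generations: int = 3
    nv: int = 4
    dtv: float = 0.5
    dtg: float = 0.5
    pa_cmH2O: float = 6.0
    pb_cmH2O: float = 9.0
    pe_cmH2O: float = 2.0
    solver: SolverSettings = field(default_factory=SolverSettings)
    out_dir: str = "."
    write_series: bool = False

    def base_case(self) -> BaseCase:
        return BaseCase(
            n_generations=self.n_generations, nv=self.nv,
            pa_cmH2O=self.pa_cmH2O, pb_cmH2O=self.pb_cmH2O,
            pe_cmH2O=self.pe_cmH2O, dtv=self.dtv, dtg=self.dtg,
            params=self.physical, settings=self.solver)

    def boundary(self) -> BoundaryConditions:
        return BoundaryConditions.from_cmh2o(self.pa_cmH2O, self.pb_cmH2O,
                                             self.pe_cmH2O)

    def to_dict(self) -> dict:
        return {
            "physical": self.physical.to_dict(),
            "network": {"n_generations": self.n_generations, "nv": self.nv},
            "timing": {"dtv": self.dtv, "dtg": self.dtg},
            "boundary": {"pa_cmH2O": self.pa_cmH2O, "pb_cmH2O": self.pb_cmH2O,
                         "pe_cmH2O": self.pe_cmH2O},
            "solver": {k: getattr(self.solver, k) for k in sorted(_SOLVER_KEYS)},
            "output": {"out_dir": self.out_dir, "write_series": self.write_series},
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def log_resolved(self) -> None:
        """Audit trail: log the resolved, unit-converted parameter values."""
        bc = self.boundary()
        p = self.physical
        log.info("resolved config:\n%s", self.to_yaml())
        log.info("cgs boundary pressures: pa=%.4f pb=%.4f pe=%.4f dyn/cm2",
                 bc.pa, bc.pb, bc.pe)
        log.info("derived constants: c9=%.6g cm sd=%.6g 1/cm Da=%.6g cm "
                 "Db=%.6g cm dpf=%.4f dyn/cm2", p.c9, p.sd, p.Da, p.Db, p.dpf)


def _coerce(section: str, key: str, value, template):
    cur = getattr(template, key) if template is not None else None
    try:
        if isinstance(cur, bool):
            return bool(value)
        if isinstance(cur, int) and not isinstance(cur, bool):
            if float(value) != int(value):
                raise ValueError
            return int(value)
        if isinstance(cur, float):
            return float(value)
        return value
    except (TypeError, ValueError):
        raise ValueError(f"{section}.{key}: cannot interpret {value!r}") from None


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None
                ) -> RunConfig:
    """Load and validate a YAML config; missing keys fall back to baseline.

    ``overrides`` is an optional {section: {key: value}} mapping applied on
    top of the file (used by CLI flags). Schema violations name the key path.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: top level must be a mapping")
    for section, kv in (overrides or {}).items():
        raw.setdefault(section, {})
        raw[section] = {**raw[section], **kv}

    unknown_sections = set(raw) - set(_SCHEMA)
    if unknown_sections:
        raise ValueError(f"unknown config section(s): {sorted(unknown_sections)}")
    for section, keys in _SCHEMA.items():
        sub = raw.get(section) or {}
        if not isinstance(sub, dict):
            raise ValueError(f"section {section!r} must be a mapping")
        bad = set(sub) - keys
        if bad:
            raise ValueError(
                f"unknown key(s) in section {section!r}: {sorted(bad)}")

    phys_tmpl = PhysicalParams()
    phys = {k: _coerce("physical", k, v, phys_tmpl)
            for k, v in (raw.get("physical") or {}).items()}
    solver_tmpl = SolverSettings()
    solver = {k: _coerce("solver", k, v, solver_tmpl)
              for k, v in (raw.get("solver") or {}).items()}
    cfg_tmpl = RunConfig()
    flat = {}
    for section in ("network", "timing", "boundary", "output"):
        for k, v in (raw.get(section) or {}).items():
            flat[k] = _coerce(section, k, v, cfg_tmpl)

    cfg = RunConfig(physical=PhysicalParams(**phys),
                    solver=SolverSettings(**solver), **flat)
    cfg.log_resolved()
    return cfg
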