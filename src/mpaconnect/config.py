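"""Run configuration (YAML) and run manifests.

A configuration file has up to four sections: ``domain`` (synthetic domain
parameters), ``simulation`` (tracker parameters), ``scenarios`` (sensitivity
plan) and ``outputs``. Unknown keys are rejected; absent keys take the
package defaults (eps = 1e-9 m^2 s^-3, dt = 7200 s, PLD = 30 d, 10 events
every 3 d, 1000 larvae/event, release at 0.2 m, daily records).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from typing import Optional

import yaml

from . import __version__
from .grids import ValidationError
from .stats import ScenarioPlan
from .synth import SyntheticDomainConfig
from .tracker import SimulationConfig, choose_time_step

SECTIONS = {"domain": SyntheticDomainConfig, "simulation": SimulationConfig,
            "scenarios": ScenarioPlan}


@dataclass
class RunConfig:
    domain: SyntheticDomainConfig
    simulation: SimulationConfig
    scenarios: ScenarioPlan
    outputs: dict

    def check_dt_admissible(self, cell_length_m: float, max_speed: float) -> None:
        if max_speed <= 0:
            return
        bound = choose_time_step(cell_length_m, max_speed)
        if self.simulation.dt_s > bound:
            raise ValidationError(
                f"dt = {self.simulation.dt_s} s exceeds the admissibility bound "
                f"cell/max_speed = {bound:.0f} s")


def _build_section(cls, data: dict, section: str):
    fields = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
    unknown = set(data) - fields
    if unknown:
        raise ValidationError(f"unknown keys in [{section}]: {sorted(unknown)}")
    coerced = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    return cls(**coerced)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration, filling all defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config root must be a mapping")
    unknown = set(raw) - set(SECTIONS) - {"outputs"}
    if unknown:
        raise ValidationError(f"unknown config sections: {sorted(unknown)}")
    parts = {name: _build_section(cls, raw.get(name, {}) or {}, name)
             for name, cls in SECTIONS.items()}
    return RunConfig(outputs=raw.get("outputs", {}) or {}, **parts)


def dump_config(cfg: RunConfig, path) -> None:
    data = {name: dataclasses.asdict(getattr(cfg, name)) for name in SECTIONS}
    data["outputs"] = cfg.outputs
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class RunManifest:
    """Traceability record: config snapshot, seeds, digests, outputs."""

    config: dict
    seed: int
    software_version: str = __version__
    input_digests: dict = dc_field(default_factory=dict)
    output_paths: dict = dc_field(default_factory=dict)
    started: Optional[str] = None
    finished: Optional[str] = None
    stage_log: list = dc_field(default_factory=list)

    def log_stage(self, name: str, **info) -> None:
        self.stage_log.append({"stage": name, "time": _now(), **info})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
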