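"""Pipeline configuration: YAML/JSON loading, defaults, strict validation."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .errors import ValidationError


@dataclasses.dataclass
class SynthBlock:
    fly_vials_per_cell: int = 40
    fly_dispersion: float = 1.5
    wasp_vials_per_cell: int = 18
    wasp_total_count_mean: float = 90.0

    def validate(self):
        if self.fly_vials_per_cell < 1:
            raise ValidationError("synth.fly_vials_per_cell", "must be >= 1")
        if self.wasp_vials_per_cell < 1:
            raise ValidationError("synth.wasp_vials_per_cell", "must be >= 1")
        if not self.fly_dispersion > 0:
            raise ValidationError("synth.fly_dispersion", "must be > 0")
        if not self.wasp_total_count_mean > 0:
            raise ValidationError("synth.wasp_total_count_mean", "must be > 0")


@dataclasses.dataclass
class SimBlock:
    K_H: float = 2000.0
    h: float = 0.01
    d: float = 0.5
    k: float = 1.0
    #: per-generation host growth multiplier gamma * r(t_base) under the
    #: G0-blind curve; gamma is derived from it at pipeline time.
    growth_target: float = 3.2
    #: initial densities; None means start at the pre-warming coexistence
    #: equilibrium of the calibrated no-TGE system.
    N0: Optional[float] = None
    P0: Optional[float] = None
    extinction_threshold: float = 1.0

    def validate(self):
        for name in ("K_H", "h", "k", "growth_target", "extinction_threshold"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"sim.{name}", f"must be > 0, got {getattr(self, name)}")
        for name in ("N0", "P0"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"sim.{name}", f"must be > 0 or null, got {v}")
        if self.d < 0:
            raise ValidationError("sim.d", "must be >= 0")


@dataclasses.dataclass
class EnvBlock:
    sigma: float = 1.0
    t_base: float = 24.0
    warming: float = 5.0
    n_burn: int = 500
    n_ramp: int = 2000
    cap: float = 30.0
    rhos: Tuple[float, ...] = (0.0, 0.8)

    def validate(self):
        if self.sigma < 0:
            raise ValidationError("env.sigma", "must be >= 0")
        for r in self.rhos:
            if not 0 <= r < 1:
                raise ValidationError("env.rhos", f"each rho must be in [0, 1), got {r}")
        if self.n_burn < 0 or self.n_ramp < 1:
            raise ValidationError("env.n_ramp", "need n_burn >= 0 and n_ramp >= 1")


@dataclasses.dataclass
class ExperimentBlock:
    n_seeds: int = 100
    models: Tuple[str, ...] = ("A", "B")

    def validate(self):
        if self.n_seeds < 2:
            raise ValidationError("experiment.n_seeds", "must be >= 2")
        for m in self.models:
            if m not in ("A", "B"):
                raise ValidationError("experiment.models", f"must be 'A' or 'B', got {m!r}")


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 0
    fly_data: Optional[str] = None   # paths to existing vial CSVs; None -> synthesize
    wasp_data: Optional[str] = None
    fit_n_starts: int = 20
    synth: SynthBlock = dataclasses.field(default_factory=SynthBlock)
    sim: SimBlock = dataclasses.field(default_factory=SimBlock)
    env: EnvBlock = dataclasses.field(default_factory=EnvBlock)
    experiment: ExperimentBlock = dataclasses.field(default_factory=ExperimentBlock)

    def validate(self):
        self.synth.validate()
        self.sim.validate()
        self.env.validate()
        self.experiment.validate()
        for name in ("fly_data", "wasp_data"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(name, f"path does not exist: {p}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(block_cls, data: dict, prefix: str):
    known = {f.name for f in dataclasses.fields(block_cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(prefix or "config", f"unknown key(s) {sorted(unknown)}")
    if "rhos" in data:
        data["rhos"] = tuple(data["rhos"])
    if "models" in data:
        data["models"] = tuple(data["models"])
    return block_cls(**data)


def load_config(path=None, strict: bool = True) -> PipelineConfig:
    """Load a YAML (or JSON) config; an empty/missing file yields defaults.

    Unknown keys raise :class:`ValidationError` in strict mode; all numeric
    fields are range-checked with the offending field named.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config", "top level must be a mapping")
    top_known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - top_known
    if unknown and strict:
        raise ValidationError("config", f"unknown top-level key(s) {sorted(unknown)}")
    kwargs = {}
    for name, cls in (("synth", SynthBlock), ("sim", SimBlock), ("env", EnvBlock),
                      ("experiment", ExperimentBlock)):
        kwargs[name] = _build(cls, dict(raw.get(name) or {}), name)
    for name in ("seed", "fly_data", "wasp_data", "fit_n_starts"):
        if name in raw:
            kwargs[name] = raw[name]
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg
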