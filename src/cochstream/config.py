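"""Run configuration: TOML schema, defaults, validation.

One TOML file describes a run: membrane, fluid, geometry, stimulus,
particle and solver sections.  Every field has a default matching the
calibrated gerbil model, so an empty file is a valid configuration.
Validation errors carry the dotted field path.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .geometry import FluidProperties
from .membrane import MembraneProperties, Tone, TonotopicMap
from .particles import ParticleProperties
from .stimulus import ToneComb, comb_from_delta, comb_from_ratio, default_f1

__all__ = ["ConfigError", "RunConfig", "load_config"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Configuration problem, annotated with the offending field path."""

    def __init__(self, path: str, message: str):
        super().__init__(f"{path}: {message}")
        self.path = path


@dataclass
class StimulusConfig:
    kind: str = "tone"            # "tone" or "comb"
    f: float = 20000.0            # tone frequency (Hz)
    spl: float = 80.0             # level, all tones (dB SPL)
    f1: float | None = None       # lowest comb frequency (Hz); derived if None
    n: int = 10                   # number of comb tones
    delta: float | None = 330e-6  # comb peak spacing (m)
    R: float | None = None        # comb frequency ratio (alternative to delta)
    x_top: float = 0.25e-3        # anchor place of the highest tone (m)
    random_phases: bool = False


@dataclass
class GeometryConfig:
    L: float = 7e-3
    h: float = 0.5e-3
    helicotrema_len: float = 0.5e-3


@dataclass
class SolverConfig:
    resolution: str = "default"          # coarse / default / fine
    attenuation: str = "compensated"     # WKB envelope mode
    include_slip: bool = True
    place_mode: str = "peak"             # characteristic-place definition


@dataclass
class TransportConfig:
    duration: float = 3600.0             # mean-flow advection time (s)
    chamber: str = "lower"
    x_start: float = 0.25e-3
    x_end: float = 3e-3


@dataclass
class RunConfig:
    membrane: MembraneProperties = field(default_factory=MembraneProperties)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    particles: ParticleProperties = field(default_factory=ParticleProperties)
    solver: SolverConfig = field(default_factory=SolverConfig)
    transport: TransportConfig = field(default_factory=TransportConfig)
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def tones(self) -> list[Tone]:
        """Resolve the stimulus into a list of tones."""
        s = self.stimulus
        if s.kind == "tone":
            return [Tone(f=s.f, spl=s.spl)]
        return list(self.comb().tones)

    def comb(self) -> ToneComb:
        s = self.stimulus
        if s.kind != "comb":
            raise ConfigError("stimulus.kind", "not a comb stimulus")
        tmap = TonotopicMap.from_membrane(self.membrane)
        domain = (0.0, self.geometry.L)
        if s.R is not None:
            f1 = s.f1 if s.f1 is not None else default_f1(
                tmap, s.n, tmap.slope * math.log(s.R), s.x_top)
            comb = comb_from_ratio(tmap, f1, s.n, s.R, spl=s.spl, domain=domain)
        else:
            if s.delta is None:
                raise ConfigError("stimulus", "comb needs delta or R")
            f1 = s.f1 if s.f1 is not None else default_f1(
                tmap, s.n, s.delta, s.x_top)
            comb = comb_from_delta(tmap, f1, s.n, s.delta, spl=s.spl,
                                   domain=domain)
        if s.random_phases:
            comb = comb.with_random_phases(self.seed)
        return comb

    def to_dict(self) -> dict:
        doc = {
            "schema_version": self.schema_version,
            "seed": self.seed,
            "membrane": asdict(self.membrane),
            "fluid": asdict(self.fluid),
            "geometry": asdict(self.geometry),
            "stimulus": asdict(self.stimulus),
            "particles": asdict(self.particles),
            "solver": asdict(self.solver),
            "transport": asdict(self.transport),
        }
        return doc


_SECTION_TYPES = {
    "geometry": GeometryConfig,
    "stimulus": StimulusConfig,
    "solver": SolverConfig,
    "transport": TransportConfig,
    "fluid": FluidProperties,
    "particles": ParticleProperties,
}


def _build_section(name, cls, data):
    fields = {f for f in cls.__dataclass_fields__}
    for key in data:
        if key not in fields:
            raise ConfigError(f"{name}.{key}", "unknown field")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(name, str(exc)) from exc


def _build_membrane(data: dict) -> MembraneProperties:
    data = dict(data)
    width = data.pop("strip_width", None)
    breadth = data.pop("strip_breadth", None)
    if (width is None) != (breadth is None):
        raise ConfigError("membrane", "strip_width and strip_breadth go together")
    if width is not None:
        data["A"] = float(width) * float(breadth)
    if "xi_by_spl" in data:
        try:
            data["xi_by_spl"] = {float(k): float(v)
                                 for k, v in data["xi_by_spl"].items()}
        except (TypeError, ValueError) as exc:
            raise ConfigError("membrane.xi_by_spl", str(exc)) from exc
    return _build_section("membrane", MembraneProperties, data)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a TOML run configuration (all fields optional)."""
    doc: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            try:
                doc = tomllib.load(fh)
            except tomllib.TOMLDecodeError as exc:
                raise ConfigError(str(path), f"invalid TOML: {exc}") from exc
    if overrides:
        doc = {**doc, **overrides}

    version = doc.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError("schema_version",
                          f"unsupported version {version} (expected {SCHEMA_VERSION})")
    seed = doc.pop("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("seed", "must be an integer")

    kwargs = {"seed": seed, "schema_version": version}
    if "membrane" in doc:
        kwargs["membrane"] = _build_membrane(doc.pop("membrane"))
    for name, cls in _SECTION_TYPES.items():
        if name in doc:
            kwargs[name] = _build_section(name, cls, doc.pop(name))
    if doc:
        raise ConfigError(next(iter(doc)), "unknown section")
    cfg = RunConfig(**kwargs)

    s = cfg.stimulus
    if s.kind not in ("tone", "comb"):
        raise ConfigError("stimulus.kind", "must be 'tone' or 'comb'")
    if s.kind == "tone" and s.f <= 0:
        raise ConfigError("stimulus.f", "must be positive")
    if s.kind == "comb" and s.n < 1:
        raise ConfigError("stimulus.n", "must be >= 1")
    if cfg.solver.resolution not in ("coarse", "default", "fine"):
        raise ConfigError("solver.resolution",
                          "must be coarse, default or fine")
    if cfg.solver.attenuation not in ("compensated", "full"):
        raise ConfigError("solver.attenuation",
                          "must be 'compensated' or 'full'")
    return cfg
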