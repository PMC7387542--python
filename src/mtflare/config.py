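"""Configuration loading and run manifests.

One YAML file fully determines a run.  Sections map onto the
parameter dataclasses ([mechanics], [interaction], [kinetics],
[nucleotide_effect], [ring], [simulation], [protocol]); unknown
sections or keys are rejected, missing ones take the documented
defaults, and the fully resolved bundle can be echoed back for the
run manifest.  All randomness flows from one master seed; components
derive their sub-streams deterministically from it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__, constants
from .energetics import InteractionParams, MechanicalParams, RingParams
from .lattice_sim import KineticParams, NucleotideEffect


class ConfigError(ValueError):
    pass


@dataclass
class SimulationSection:
    dt: float = 2.0e-12
    T: float = constants.T_DEFAULT
    eta: float = constants.ETA_DEFAULT
    seed: int = 0
    duration: float = 1.0e-5
    record_stride: int = 1000
    n_monomers: int = 16

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must be >= dt")


@dataclass
class ProtocolSection:
    duration: float = 0.5
    bd_window: Optional[float] = None
    dilution: bool = False
    hydrolysis: bool = True
    n_dimers: int = 20
    mobile_dimers: int = 8
    nucleotide: str = "GTP"
    cap_dimers: int = 0
    cap_length: float = 110.0
    snapshot_every: int = 0
    wall_tolerance: float = 1.5

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.nucleotide.upper() not in ("GTP", "GDP"):
            raise ValueError("nucleotide must be GTP or GDP")


_SECTIONS = {
    "mechanics": MechanicalParams,
    "interaction": InteractionParams,
    "kinetics": KineticParams,
    "nucleotide_effect": NucleotideEffect,
    "ring": RingParams,
    "simulation": SimulationSection,
    "protocol": ProtocolSection,
}


@dataclass
class RunConfig:
    """Fully resolved parameter bundle for one run."""

    mechanics: MechanicalParams = field(default_factory=MechanicalParams)
    interaction: InteractionParams = field(default_factory=InteractionParams)
    kinetics: KineticParams = field(default_factory=KineticParams)
    nucleotide_effect: NucleotideEffect = field(
        default_factory=NucleotideEffect)
    ring: RingParams = field(default_factory=RingParams)
    simulation: SimulationSection = field(default_factory=SimulationSection)
    protocol: ProtocolSection = field(default_factory=ProtocolSection)

    def to_dict(self) -> dict:
        out = {}
        for name in _SECTIONS:
            sec = getattr(self, name)
            d = dataclasses.asdict(sec)
            d.pop("E_depth", None)  # derived, not free
            out[name] = d
        return out


def _build_section(name: str, cls, data: dict):
    allowed = {f.name for f in dataclasses.fields(cls) if f.init}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section [{name}]; "
            f"allowed: {sorted(allowed)}")
    try:
        return cls(**data)
    except ValueError as exc:
        raise ConfigError(f"invalid value in section [{name}]: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; missing keys take defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping of sections")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(
            f"unknown section(s) {sorted(unknown)}; "
            f"allowed: {sorted(_SECTIONS)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        data = raw.get(name) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"section [{name}] must be a mapping")
        kwargs[name] = _build_section(name, cls, data)
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# manifests


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: RunConfig, seed: int,
                   outputs: list, extra: Optional[dict] = None) -> Path:
    """One manifest per output directory: config snapshot, seed,
    version, and a content hash per output file."""
    out_dir = Path(out_dir)
    manifest = {
        "package": "mtflare",
        "version": __version__,
        "seed": seed,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config.to_dict(),
        "outputs": {str(Path(p).name): file_sha256(p) for p in outputs},
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
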