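"""Run configuration: a YAML-serialisable bundle of every stage's
parameters, with defaults matching the study protocol (TE 20 ms,
alpha 0.0094 ppm/°C, 2 °C masking threshold, 240 EM, 40 W x 30 s on
3/6/9 mm circles).  Unknown keys are rejected with their key path so a
typo never silently falls back to a default."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .dose import DoseConfig
from .errors import ConfigError
from .geometry import ScanGrid
from .masking import MaskingConfig
from .phantom import SignalModel, SimGrid3D, SonicationProtocol, TransducerModel
from .thermometry import AcquisitionParams, ThermometryConfig

__all__ = ["StudyDesign", "RunConfig", "load_config", "save_config", "config_hash"]


@dataclass(frozen=True)
class StudyDesign:
    """Cohort layout and calibration target of one study run.

    ``markers`` are catalogue names; a reference phantom without marker
    is always included.  Each phantom receives ``n_reference``
    sonications away from the marker (absorption calibration) and
    ``n_on_marker`` sonications centred on it.
    """

    markers: tuple[str, ...] = ()
    n_on_marker: int = 6
    n_reference: int = 6
    absorption_sd: float = 0.046
    target_peak_C: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_on_marker < 1 or self.n_reference < 1:
            raise ConfigError("sonication counts must be >= 1")
        if not 0 <= self.absorption_sd < 1:
            raise ConfigError("absorption_sd must be in [0, 1)")


_SECTIONS: dict[str, type] = {
    "protocol": SonicationProtocol,
    "acq": AcquisitionParams,
    "thermo": ThermometryConfig,
    "masking": MaskingConfig,
    "dose": DoseConfig,
    "signal": SignalModel,
    "transducer": TransducerModel,
    "sim_grid": SimGrid3D,
    "scan_grid": ScanGrid,
    "study": StudyDesign,
}


@dataclass(frozen=True)
class RunConfig:
    """Fully explicit configuration of a study run."""

    protocol: SonicationProtocol = field(default_factory=SonicationProtocol)
    acq: AcquisitionParams = field(default_factory=AcquisitionParams)
    thermo: ThermometryConfig = field(default_factory=ThermometryConfig)
    masking: MaskingConfig = field(default_factory=MaskingConfig)
    dose: DoseConfig = field(default_factory=DoseConfig)
    signal: SignalModel = field(default_factory=SignalModel)
    transducer: TransducerModel = field(default_factory=TransducerModel)
    sim_grid: SimGrid3D = field(default_factory=SimGrid3D)
    scan_grid: ScanGrid = field(default_factory=ScanGrid)
    study: StudyDesign = field(default_factory=StudyDesign)
    time_step_s: float = 0.25

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for name in _SECTIONS:
            section = dataclasses.asdict(getattr(self, name))
            for k, v in section.items():
                if isinstance(v, tuple):
                    section[k] = list(v)
            out[name] = section
        out["time_step_s"] = self.time_step_s
        return out


def _build_section(name: str, cls: type, data: dict) -> Any:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {name!r}")
    kwargs = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {name!r}: {exc}") from exc


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    data = dict(data or {})
    kwargs: dict[str, Any] = {}
    time_step = data.pop("time_step_s", 0.25)
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        kwargs[name] = _build_section(name, cls, section)
    return RunConfig(time_step_s=float(time_step), **kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration, filling defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    return config_from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the canonical serialised configuration."""
    canonical = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
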