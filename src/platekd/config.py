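"""Structured run configuration: instrument, evaporation, anomalies, fitting.

A YAML file with (all optional) ``instrument``, ``evaporation``,
``anomalies``, ``schedule`` and ``fit`` sections maps onto the parameter
dataclasses; unknown keys are rejected so typos never silently fall back
to defaults.  Every default is echoed back into outputs for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dls_simulator import AnomalySpec, EvaporationParams, InstrumentConfig


@dataclass(frozen=True)
class FitSettings:
    """Analysis-side knobs: screening and cumulant acceptance thresholds."""

    screen_outliers: bool = True
    grubbs_alpha: float = 0.05
    max_removals: int = 2
    sos_threshold: float = 20.0
    pdi_threshold: float = 0.3


@dataclass(frozen=True)
class ScheduleSettings:
    dwell_s: float = 75.0
    order: str = "row_major"


@dataclass
class RunConfig:
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    evaporation: EvaporationParams = field(default_factory=EvaporationParams)
    anomalies: AnomalySpec = field(default_factory=AnomalySpec)
    schedule: ScheduleSettings = field(default_factory=ScheduleSettings)
    fit: FitSettings = field(default_factory=FitSettings)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


_SECTIONS = {
    "instrument": InstrumentConfig,
    "evaporation": EvaporationParams,
    "anomalies": AnomalySpec,
    "schedule": ScheduleSettings,
    "fit": FitSettings,
}


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; ``None`` gives all defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        entries = raw.get(section, {}) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(entries) - valid
        if bad:
            raise ValueError(f"unknown keys {sorted(bad)} in config section {section!r}")
        kwargs[section] = cls(**entries)
    return RunConfig(**kwargs)
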