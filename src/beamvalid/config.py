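"""Validation-run configuration: one YAML file describing the whole loop.

The file groups the protocol request, beam-model parameters, noise and
chamber models, TPS sampling settings, the list of gamma criteria and the
random seed.  Every section is optional; omitted fields take the package
defaults, which reproduce the published validation protocol (5 square
fields 6-28 cm, profile depths 1.3-30 cm, diagonals for 28x28 only).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .beam import BeamModelParams
from .gamma import GammaCriteria
from .measure import ChamberModel, NoiseModel
from .protocol import ProtocolConfig, ScanAxisConfig
from .tps import SpacingRule

__all__ = ["TpsSamplingConfig", "PerturbationConfig", "ValidationRunConfig",
           "load_config", "save_config"]


@dataclass(frozen=True)
class TpsSamplingConfig:
    """How the TPS-side curves are extracted."""

    rule: SpacingRule = field(default_factory=SpacingRule)
    depth_spacing_mm: float = 5.0
    voxel_cm: float = 0.5
    window_pad_cm: float = 0.5


@dataclass(frozen=True)
class PerturbationConfig:
    """Deliberate measurement-side perturbations for discrimination studies.

    edge_shift_mm moves both field edges of the measurement-side beam
    outward (a geometric/penumbra error).  dose_scale_pct scales the
    normalized measured curves (a net dose discrepancy in comparison
    space; a physical uniform output error cancels under relative
    normalization, see the methods note).
    """

    edge_shift_mm: float = 0.0
    dose_scale_pct: float = 0.0

    @property
    def is_null(self) -> bool:
        return self.edge_shift_mm == 0.0 and self.dose_scale_pct == 0.0


def _default_criteria() -> tuple:
    return (GammaCriteria(1.0, 1.0), GammaCriteria(1.5, 1.5))


@dataclass(frozen=True)
class ValidationRunConfig:
    """Everything needed to run the closed validation loop."""

    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    beam: BeamModelParams = field(default_factory=BeamModelParams)
    noise: NoiseModel = field(default_factory=NoiseModel)
    chamber: ChamberModel = field(default_factory=ChamberModel)
    tps: TpsSamplingConfig = field(default_factory=TpsSamplingConfig)
    gamma_criteria: tuple = field(default_factory=_default_criteria)
    perturbation: PerturbationConfig = field(default_factory=PerturbationConfig)
    seed: int = 0

    def strictest_criteria(self) -> GammaCriteria:
        """The criteria with the smallest tolerances (used for the verdict)."""
        return min(self.gamma_criteria, key=lambda c: (c.dose_pct, c.dta_mm))


def _build(cls, data: dict | None):
    """Construct a (possibly nested) dataclass from a mapping, keeping
    defaults for omitted fields."""
    data = dict(data or {})
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data.pop(f.name)
        sub = _NESTED.get((cls, f.name))
        if sub is not None and isinstance(value, dict):
            value = _build(sub, value)
        elif (cls, f.name) == (ProtocolConfig, "axis_configs"):
            value = {axis: _build(ScanAxisConfig, cfg) if isinstance(cfg, dict) else cfg
                     for axis, cfg in value.items()}
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    if data:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(data)}")
    return cls(**kwargs)


_NESTED = {
    (ValidationRunConfig, "protocol"): ProtocolConfig,
    (ValidationRunConfig, "beam"): BeamModelParams,
    (ValidationRunConfig, "noise"): NoiseModel,
    (ValidationRunConfig, "chamber"): ChamberModel,
    (ValidationRunConfig, "tps"): TpsSamplingConfig,
    (ValidationRunConfig, "perturbation"): PerturbationConfig,
    (TpsSamplingConfig, "rule"): SpacingRule,
}


def config_from_dict(data: dict) -> ValidationRunConfig:
    data = dict(data)
    criteria = data.pop("gamma_criteria", None)
    cfg = _build(ValidationRunConfig, data)
    if criteria is not None:
        crits = tuple(_build(GammaCriteria, c) for c in criteria)
        cfg = dataclasses.replace(cfg, gamma_criteria=crits)
    return cfg


def config_to_dict(cfg: ValidationRunConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: clean(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        return obj

    return clean(cfg)


def load_config(path: str | Path | None) -> ValidationRunConfig:
    """Load a YAML run config; ``None`` returns the defaults."""
    if path is None:
        return ValidationRunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(data)


def save_config(cfg: ValidationRunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
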