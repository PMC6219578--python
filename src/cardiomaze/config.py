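"""YAML configuration for the pipeline stages.

A configuration tree has up to four sections -- ``cell``, ``tissue``,
``lesion`` and ``sweep`` -- each mapping onto the keyword arguments of the
corresponding dataclasses.  Unknown keys are rejected with the path to the
offending key; omitted keys take the package defaults; a save/load round
trip is the identity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .ionic_model import IschemiaParams, KatpConstants, StimulusTrain
from .monte_carlo import SweepDesign

__all__ = ["CellConfig", "TissueConfig", "LesionConfig", "Config",
           "load_config", "save_config"]


@dataclass(frozen=True)
class CellConfig:
    isch: IschemiaParams = field(default_factory=IschemiaParams)
    katp: KatpConstants = field(default_factory=KatpConstants)
    pacing: StimulusTrain = field(default_factory=StimulusTrain)
    dt: float = 0.02          # ms
    sample_every: float = 1.0  # ms

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("cell.dt must be positive")


@dataclass(frozen=True)
class TissueConfig:
    dims: tuple = (100, 1, 1)
    spacing: float = 100.0    # um
    sigma: float = 1.85       # mS/cm
    beta: float = 1400.0      # 1/cm
    cm: float = 1.0           # uF/cm^2
    dt: float = 0.02          # ms
    duration: float = 200.0   # ms
    snapshot_every: float = 5.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("tissue.dt must be positive")
        if self.spacing <= 0:
            raise ValueError("tissue.spacing must be positive")


@dataclass(frozen=True)
class LesionConfig:
    scar_radius: float = 2000.0      # um
    pz_outer_radius: float = 2600.0  # um
    phi_scar: float = 0.66
    atp_scar: float = 2.0            # mM


@dataclass(frozen=True)
class Config:
    cell: CellConfig = field(default_factory=CellConfig)
    tissue: TissueConfig = field(default_factory=TissueConfig)
    lesion: LesionConfig = field(default_factory=LesionConfig)
    sweep: SweepDesign = field(default_factory=SweepDesign)


_NESTED = {
    "isch": IschemiaParams, "katp": KatpConstants, "pacing": StimulusTrain,
    "cell": CellConfig, "tissue": TissueConfig, "lesion": LesionConfig,
    "sweep": SweepDesign,
}

_TUPLE_KEYS = {"dims", "phi_values", "atp_values"}


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        here = f"{path}.{key}" if path else key
        if key not in names:
            raise ValueError(f"unknown configuration key: {here}")
        if isinstance(value, dict) and key in _NESTED:
            value = _build(_NESTED[key], value, here)
        elif key in _TUPLE_KEYS and isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> Config:
    """Load and validate a YAML configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration root must be a mapping")
    return _build(Config, data, "")


def _as_dict(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _as_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(config: Config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_as_dict(config), fh, sort_keys=False)
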