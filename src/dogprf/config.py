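"""Run configuration: one YAML file describing every pipeline stage.

The parameter space (visual-field grid, protocol timing, HRF shape, coarse
search lattice, noise and generator settings, screening thresholds) is too
wide for command-line flags, so each CLI command reads a single config file
with per-section keys and writes a snapshot of the resolved configuration
beside its outputs; an artifact directory is reproducible from its snapshot
alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dog_model import VisualFieldGrid
from .errors import ConfigError
from .fitting import FitOptions, SearchSpace
from .forward_model import HRFModel
from .stimulus import ProtocolConfig
from .synthetic import GroundTruthConfig, NoiseModel


@dataclass(frozen=True)
class Thresholds:
    r2_screening: float = 0.05
    delta_bounds: tuple[float, float] = (0.1, 0.9)
    balance_tolerance: float = 1e-6
    bias_bounds: tuple[float, ...] = (1.0, 5.0)


@dataclass(frozen=True)
class RunConfig:
    """Aggregate configuration for every pipeline command."""

    grid: VisualFieldGrid = field(default_factory=VisualFieldGrid)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    hrf: HRFModel = field(default_factory=HRFModel)
    search: SearchSpace = field(default_factory=SearchSpace)
    fit: FitOptions = field(default_factory=FitOptions)
    noise: NoiseModel = field(default_factory=NoiseModel)
    truth: GroundTruthConfig = field(default_factory=GroundTruthConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    n_voxels: int = 100
    normalise: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if hasattr(obj, "item"):  # numpy scalar
                return obj.item()
            return obj

        return {f.name: clean(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sections = {
            "grid": VisualFieldGrid,
            "protocol": ProtocolConfig,
            "hrf": HRFModel,
            "search": SearchSpace,
            "fit": FitOptions,
            "noise": NoiseModel,
            "truth": GroundTruthConfig,
            "thresholds": Thresholds,
        }
        kwargs = {}
        for key, value in data.items():
            if key in sections:
                if not isinstance(value, dict):
                    raise ConfigError(f"section '{key}' must be a mapping")
                factory = sections[key]
                names = {f.name for f in dataclasses.fields(factory)}
                unknown = set(value) - names
                if unknown:
                    raise ConfigError(f"unknown keys in '{key}': {sorted(unknown)}")
                coerced = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
                }
                try:
                    kwargs[key] = factory(**coerced)
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"invalid section '{key}': {exc}") from exc
            elif key in {"n_voxels", "normalise", "seed"}:
                kwargs[key] = value
            else:
                raise ConfigError(f"unknown config key '{key}'")
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)


def study_defaults(seed: int = 0) -> RunConfig:
    """The package's default synthetic-study conditions.

    A 51x51 analysis grid over +/-17.4 deg keeps the per-evaluation cost of
    the fitter modest while sampling the smallest simulated receptive
    fields (sigma2 >= 0.5 deg) with several cells per sigma; protocol,
    HRF, search-space and noise settings are the package defaults.
    """
    return RunConfig(grid=VisualFieldGrid(17.4, 51), seed=seed,
                     noise=NoiseModel(seed=seed))
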