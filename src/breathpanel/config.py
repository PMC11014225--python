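"""Run configuration: nested sections mirroring each pipeline stage.

Configs load from a YAML mapping; unknown keys are rejected so typos fail
loudly.  Every run writes its fully resolved configuration next to its
outputs for reproducibility.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import SimulationConfig

__all__ = ["RunConfig", "PreprocessConfig", "PeaksConfig", "DiscoverConfig", "EvaluateConfig"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class PreprocessConfig:
    window: int = 21
    polyorder: int = 3
    smoothness: float = 1e9
    asymmetry: float = 0.01
    max_iter: int = 10
    floor_fraction: float = 0.01
    ceiling: float | None = None
    n_anchors: int = 6
    min_anchors: int = 2
    max_saturation: float = 0.05


@dataclass
class PeaksConfig:
    min_snr: float = 5.0
    min_prominence: float | None = None
    tolerance: float = 3.0
    min_presence: float = 0.5


@dataclass
class DiscoverConfig:
    k: int = 3
    mode: str = "exhaustive"
    shrinkage: float = 0.1
    max_subsets: int = 1_000_000
    top_results: int = 1000  # ranked subsets written to CSV


@dataclass
class EvaluateConfig:
    shrinkage: float = 0.1
    refit_pca_all: bool = False


@dataclass
class RunConfig:
    """Top-level pipeline configuration.

    Either a ``simulate`` section must be present (synthetic cohort) or
    ``input_dir`` must point at a directory of chromatogram CSVs plus a
    ``manifest.csv``.  The global ``seed`` overrides the simulate section's
    seed so one integer controls every source of randomness.
    """

    seed: int = 0
    input_dir: str | None = None
    log_level: str = "INFO"
    simulate: SimulationConfig | None = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    peaks: PeaksConfig = field(default_factory=PeaksConfig)
    discover: DiscoverConfig = field(default_factory=DiscoverConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)

    def __post_init__(self) -> None:
        if self.simulate is None and self.input_dir is None:
            raise ConfigError("either a simulate section or input_dir is required")
        if self.simulate is not None:
            self.simulate.seed = self.seed

    # -- (de)serialization ------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        sections = {
            "simulate": SimulationConfig,
            "preprocess": PreprocessConfig,
            "peaks": PeaksConfig,
            "discover": DiscoverConfig,
            "evaluate": EvaluateConfig,
        }
        kwargs: dict = {}
        for key, section_cls in sections.items():
            if key in data:
                raw = data.pop(key)
                if raw is None:
                    kwargs[key] = None
                else:
                    kwargs[key] = _build(section_cls, raw, where=key)
        top_fields = {f.name for f in dataclasses.fields(cls)} - set(sections)
        for key in list(data):
            if key not in top_fields:
                raise ConfigError(f"unknown configuration key: {key!r}")
            kwargs[key] = data.pop(key)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        def _plain(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: _plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, (tuple, list)):
                return [_plain(v) for v in obj]
            return obj

        return _plain(self)

    def write_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _build(section_cls, raw: dict, where: str):
    if not isinstance(raw, dict):
        raise ConfigError(f"section {where!r} must be a mapping")
    names = {f.name for f in dataclasses.fields(section_cls)}
    unknown = set(raw) - names
    if unknown:
        raise ConfigError(f"unknown key(s) in section {where!r}: {sorted(unknown)}")
    kwargs = dict(raw)
    # YAML lists arrive as lists; tuple-typed fields want tuples
    for f in dataclasses.fields(section_cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return section_cls(**kwargs)
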