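"""Run configuration: validated, echoable, with unknown keys rejected.

The YAML layout mirrors the pipeline stages::

    tile_size: 32
    classifier:
      kind: heuristic            # heuristic | oracle | external
      min_contrast: 40.0
      min_fraction: 0.05
      max_fraction: 0.80
      labels_path: null          # external kind: per-tile label CSV
    rpe:
      strategy: flood_fill       # flood_fill | merged_block | single_tile
    oct:
      directions: five           # five | three | explicit list
      rules: true
      max_angle_step: 45.0
      length_tolerance_rel: 0.25
      length_tolerance_abs: 2.0
      tolerance_mode: hybrid     # hybrid | window
      keep_top_n: 1
    diameter:
      n_bins: 5

Command-line flags override file values; the effective configuration is
echoed into every run's output directory so runs are reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cover import CoverRuleConfig, FIVE_DIRECTIONS, THREE_DIRECTIONS

__all__ = ["ClassifierConfig", "RpeConfig", "OctConfig", "DiameterConfig",
           "RunConfig"]


@dataclass
class ClassifierConfig:
    kind: str = "heuristic"
    min_contrast: float = 40.0
    min_fraction: float = 0.05
    max_fraction: float = 0.80
    labels_path: str | None = None


@dataclass
class RpeConfig:
    strategy: str = "flood_fill"


@dataclass
class OctConfig:
    directions: str | list[str] = "five"
    rules: bool = True
    max_angle_step: float = 45.0
    length_tolerance_rel: float = 0.25
    length_tolerance_abs: float = 2.0
    tolerance_mode: str = "hybrid"
    keep_top_n: int = 1

    def to_rule_config(self) -> CoverRuleConfig:
        if self.directions == "five":
            dirs = FIVE_DIRECTIONS
        elif self.directions == "three":
            dirs = THREE_DIRECTIONS
        else:
            dirs = tuple(self.directions)
        return CoverRuleConfig(
            directions=dirs,
            max_angle_step=self.max_angle_step,
            length_tolerance_rel=self.length_tolerance_rel,
            length_tolerance_abs=self.length_tolerance_abs,
            rules_enabled=self.rules,
            tolerance_mode=self.tolerance_mode,
            keep_top_n=self.keep_top_n,
        )


@dataclass
class DiameterConfig:
    n_bins: int = 5


@dataclass
class RunConfig:
    tile_size: int = 32
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    rpe: RpeConfig = field(default_factory=RpeConfig)
    oct: OctConfig = field(default_factory=OctConfig)
    diameter: DiameterConfig = field(default_factory=DiameterConfig)
    verbosity: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _build(cls, data, context="run config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def validate(self) -> "RunConfig":
        from .rpe import STRATEGIES

        if self.tile_size < 1:
            raise ValueError("tile_size must be >= 1")
        if self.rpe.strategy not in STRATEGIES:
            raise ValueError(f"unknown RPE strategy {self.rpe.strategy!r}")
        if self.classifier.kind not in ("heuristic", "oracle", "external"):
            raise ValueError(f"unknown classifier kind {self.classifier.kind!r}")
        if self.diameter.n_bins < 1:
            raise ValueError("diameter.n_bins must be >= 1")
        self.oct.to_rule_config()  # raises on bad direction/tolerance settings
        return self


def _build(cls, data: dict, context: str):
    """Instantiate a (possibly nested) config dataclass, rejecting unknown keys."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown {context} keys: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].default_factory if fields[name].default_factory is not dataclasses.MISSING else None
        if ftype is not None and isinstance(value, dict):
            kwargs[name] = _build(ftype, value, context=name)
        else:
            kwargs[name] = value
    return cls(**kwargs)
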