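"""Pipeline configuration (YAML/JSON), with strict unknown-key rejection."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import SchemaError


@dataclass
class PipelineConfig:
    """Everything the pipeline stages need, with explicit seeds."""

    fps: float = 30.0
    standing_s: float = 1.0
    feature_mode: str = "3d"
    smooth_window_s: float = 0.15
    prominence_deg: float = 5.0
    min_separation_s: float = 0.4
    screen_seed: int = 0
    split_seed: int = 0
    n_per_class: int = 40
    duration_s: float = 10.0
    noise_px: float = 1.0
    theta1_range: tuple[float, float] = (5.0, 25.0)
    archetype_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feature_mode not in ("2d", "3d"):
            raise SchemaError("feature_mode must be '2d' or '3d'")
        if self.fps <= 0 or self.duration_s <= 0:
            raise SchemaError("fps and duration_s must be positive")
        self.theta1_range = tuple(self.theta1_range)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise SchemaError(f"unknown config keys: {', '.join(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise SchemaError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["theta1_range"] = list(self.theta1_range)
        return d
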