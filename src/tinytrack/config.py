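"""Pipeline configuration: every downstream tunable in one flat record."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Flat, serializable bag of tunables for all pipeline stages.

    Defaults are declared choices; none are dictated by the method itself.
    """

    # detection
    sigma_u_frac: float = 0.25        # center-Gaussian sigma as fraction of min(w, h)
    sigma_p: float = 10.0             # motion-model sigma, full-resolution pixels
    downsample: int = 2               # unary grid downsample factor d
    unary_floor: float = 1e-12        # score floor before log
    subcell_refine: bool = True
    # registration
    n_keypoints: int = 1000
    match_max_ratio: float = 0.8
    ransac_threshold: float = 3.0
    keyframe_overlap: float = 0.5
    keyframe_max_gap: int = 100
    min_keyframe_matches: int = 15
    # trajectory analysis
    smooth_polyorder: int = 3
    smooth_window: int = 50
    median_window: int = 10
    mean_window: int = 10
    # misc
    fps: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool):
                continue
            if isinstance(v, (int, float)) and v <= 0 and f.name != "seed":
                raise ValueError(f"config field {f.name} must be positive, got {v}")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")
        if not 1 <= self.downsample <= 8:
            raise ValueError("downsample must be in [1, 8]")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
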