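"""Pipeline configuration: dataclass tree + YAML loading.

YAML layout mirrors the stages::

    sov:      {central_fraction: 0.5, min_object_pixels: 700, bbox_pad_fraction: 0.1}
    calcium:  {maxh_divisor: 3, dr_factor: 0.7, bright_factor: 0.5, dark_factor: 0.2,
               strict_compare: true}
    snake:    {mu: 0.2, gvf_iters: 200, gvf_tol: 1.0e-3, alpha: 0.1, beta: 0.1,
               tau: 1.0, max_iters: 500, converge_tol: 0.05, n_vertices: 100}
    pipeline: {adaptive_window: 31, adaptive_offset: 10, fill_holes: true,
               min_area_mm2: 40, calcium_exclusion: post}
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from .calcium import CalciumConfig
from .errors import ConfigurationError
from .snake import SnakeConfig
from .sov import SovConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunables of :func:`avaplan.pipeline.segment_ava`.

    ``calcium_exclusion``: "post" removes calcified pixels from the final
    orifice mask (default); "pre" removes them from the binarized image before
    the snake runs; "off" disables exclusion.
    """

    sov: SovConfig = field(default_factory=SovConfig)
    calcium: CalciumConfig = field(default_factory=CalciumConfig)
    snake: SnakeConfig = field(default_factory=SnakeConfig)
    adaptive_window: int = 31
    adaptive_offset: float = 10.0
    fill_holes: bool = True
    contour_covers_edge: bool = True
    min_area_mm2: float = 40.0
    calcium_exclusion: str = "post"

    def __post_init__(self) -> None:
        if self.calcium_exclusion not in ("post", "pre", "off"):
            raise ConfigurationError(
                f"calcium_exclusion must be post/pre/off, got {self.calcium_exclusion!r}"
            )

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        kwargs = {}
        for name, sub_cls in (("sov", SovConfig), ("calcium", CalciumConfig), ("snake", SnakeConfig)):
            sub = dict(raw.pop(name, {}) or {})
            valid = {f.name for f in dataclasses.fields(sub_cls)}
            unknown = set(sub) - valid
            if unknown:
                raise ConfigurationError(f"unknown {name} config keys: {sorted(unknown)}")
            kwargs[name] = sub_cls(**sub)
        top = dict(raw.pop("pipeline", {}) or {})
        if raw:
            raise ConfigurationError(f"unknown config sections: {sorted(raw)}")
        valid_top = {
            f.name for f in dataclasses.fields(cls) if f.name not in ("sov", "calcium", "snake")
        }
        unknown = set(top) - valid_top
        if unknown:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**kwargs, **top)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(Path(path)) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "sov": dataclasses.asdict(self.sov),
            "calcium": dataclasses.asdict(self.calcium),
            "snake": dataclasses.asdict(self.snake),
            "pipeline": {
                "adaptive_window": self.adaptive_window,
                "adaptive_offset": self.adaptive_offset,
                "fill_holes": self.fill_holes,
                "min_area_mm2": self.min_area_mm2,
                "calcium_exclusion": self.calcium_exclusion,
            },
        }
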