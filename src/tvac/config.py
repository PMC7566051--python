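"""Run configuration: every tunable of the pipeline in one serializable record."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .contour import ACMParams
from .localize import QualityParams
from .tv import TVParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline parameters; round-trips losslessly through JSON.

    ``quadrant_mode`` selects the stacked (quadrant-wise) active contour; when
    False each whole lung hull is refined in one piece (the baseline the
    stacked model improves on).
    """

    tv: TVParams = field(default_factory=TVParams)
    quality: QualityParams = field(default_factory=QualityParams)
    acm: ACMParams = field(default_factory=ACMParams)
    clahe_clip_limit: float = 0.01
    clahe_tile_grid: tuple[int, int] = (8, 8)
    overlap_fraction: float = 0.05
    quadrant_mode: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clahe_tile_grid"] = list(self.clahe_tile_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        tv = TVParams(**d.pop("tv", {}))
        quality = QualityParams(**d.pop("quality", {}))
        acm = ACMParams(**d.pop("acm", {}))
        if "clahe_tile_grid" in d:
            d["clahe_tile_grid"] = tuple(d["clahe_tile_grid"])
        return cls(tv=tv, quality=quality, acm=acm, **d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))
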