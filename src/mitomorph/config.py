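"""Run configuration: one YAML file determines an analysis completely.

Example::

    channel_map: {nucleus: 0, membrane: 1, mito: 2}
    pixel_size_um: 0.2
    segmentation:
      nucleus_smooth_sigma_px: 2.0
      nucleus_min_area_px: 200
      split_h_maxima_depth: 2.0
      cell_min_area_px: 2000
      border_policy: exclude
    morphology:
      tophat_radius_px: 8
      min_particle_area_px: 4
      connectivity: 8
    stats:
      test: welch          # or student
      star_thresholds: [0.05, 0.01, 0.001]
    seed: 0

Any omitted key falls back to the documented default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .morphology import MorphologyParams
from .segmentation import SegmentationParams

DEFAULT_CHANNEL_MAP = {"nucleus": 0, "membrane": 1, "mito": 2}


@dataclass
class StatsConfig:
    test: str = "welch"
    star_thresholds: tuple[float, float, float] = (0.05, 0.01, 0.001)

    def __post_init__(self) -> None:
        if self.test not in ("welch", "student"):
            raise ValueError("stats.test must be 'welch' or 'student'")
        self.star_thresholds = tuple(self.star_thresholds)


@dataclass
class AnalysisConfig:
    channel_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    pixel_size_um: float = 0.2
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    morphology: MorphologyParams = field(default_factory=MorphologyParams)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stats"]["star_thresholds"] = list(self.stats.star_thresholds)
        return d


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Read a YAML config; ``None`` yields all defaults."""
    if path is None:
        return AnalysisConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> AnalysisConfig:
    cfg = AnalysisConfig()
    kwargs: dict = {}
    if "channel_map" in raw:
        kwargs["channel_map"] = {str(k): int(v) for k, v in raw["channel_map"].items()}
    if "pixel_size_um" in raw:
        kwargs["pixel_size_um"] = float(raw["pixel_size_um"])
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "segmentation" in raw:
        kwargs["segmentation"] = SegmentationParams(**raw["segmentation"])
    if "morphology" in raw:
        kwargs["morphology"] = MorphologyParams(**raw["morphology"])
    if "stats" in raw:
        kwargs["stats"] = StatsConfig(**raw["stats"])
    return AnalysisConfig(**{**asdict_defaults(cfg), **kwargs})


def asdict_defaults(cfg: AnalysisConfig) -> dict:
    return {
        "channel_map": cfg.channel_map,
        "pixel_size_um": cfg.pixel_size_um,
        "segmentation": cfg.segmentation,
        "morphology": cfg.morphology,
        "stats": cfg.stats,
        "seed": cfg.seed,
    }
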