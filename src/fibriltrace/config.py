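"""Pipeline configuration with YAML round-trip support."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .io import DEFAULT_PIXEL_SIZE


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the analysis chain in one serialisable object.

    ``mask_k`` scales the robust (median + k * 1.4826 MAD) threshold of the
    background-fit feature mask; ``k_detect`` scales the detection threshold
    in units of the fitted background sigma; ``min_area_px`` drops
    single-pixel noise clusters.
    """

    pixel_size: float = DEFAULT_PIXEL_SIZE  # nm/px fallback for scale-less files
    mask_k: float = 3.0
    k_detect: float = 5.0
    min_area_px: int = 4
    poly_order: int = 2
    n_passes: int = 2
    n_bins: int = 256
    kde_grid_points: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size", "mask_k", "k_detect"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_area_px < 1 or self.n_passes < 1 or self.n_bins < 8:
            raise ValueError("min_area_px, n_passes >= 1 and n_bins >= 8 required")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def replace(self, **kwargs) -> "PipelineConfig":
        d = self.to_dict()
        d.update(kwargs)
        return self.from_dict(d)
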