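"""Pipeline configuration with lossless YAML round-tripping."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .embedding import DEFAULT_EARLY_EXAGGERATION, DEFAULT_PERPLEXITY
from .segmentation import SegmentationConfig
from .tracing import TraceConfig

__all__ = ["PipelineConfig"]

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All analysis settings for an end-to-end run.

    Segmentation and tracing defaults follow the module docs; calibration
    defaults to 0.1 µm/px laterally and 1.0 µm z-steps; the embedding uses
    perplexity 2.49 and early exaggeration 12; the scoring threshold sits
    ``sd_multiplier`` (default 1) background SDs above the background mean.
    """

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    tracing: TraceConfig = field(default_factory=TraceConfig)
    pixel_size_xy: float = 0.1
    z_step: float = 1.0
    perplexity: float = DEFAULT_PERPLEXITY
    early_exaggeration: float = DEFAULT_EARLY_EXAGGERATION
    embed_seed: int = 0
    sd_multiplier: float = 1.0
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.pixel_size_xy <= 0 or self.z_step <= 0:
            raise ValueError("calibrations must be positive")
        if self.perplexity <= 0 or self.early_exaggeration <= 0:
            raise ValueError("embedding parameters must be positive")
        if self.sd_multiplier < 0:
            raise ValueError("sd_multiplier must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        version = data.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported config schema version {version} "
                f"(this build reads version {SCHEMA_VERSION})"
            )
        seg = SegmentationConfig(**data.pop("segmentation", {}))
        trc = TraceConfig(**data.pop("tracing", {}))
        return cls(segmentation=seg, tracing=trc, schema_version=version, **data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
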