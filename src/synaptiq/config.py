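"""Run configuration: per-channel segmentation parameters and pipeline knobs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .segmentation import SegmentationParams

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    Defaults encode the quantification parameters of the source experiments:
    Mask 1 / Mask 2 threshold multipliers per channel, cSMAC definition
    (>90% of clustered antigen in at most 2 clusters), SPT at 33 Hz with
    blur coefficient 1/6, and ROUT at Q = 1%.
    """

    channels: dict[str, SegmentationParams] = field(
        default_factory=lambda: {
            "Ag": SegmentationParams(n_mask1=3, n_mask2=4),
            "pCD79": SegmentationParams(n_mask1=2, n_mask2=3),
            "pSyk": SegmentationParams(n_mask1=2, n_mask2=5),
            "pCD19": SegmentationParams(n_mask1=3, n_mask2=4),
        }
    )
    csmac_threshold: float = 0.9
    csmac_max_clusters: int = 2
    frame_interval_s: float = 1.0 / 33.0
    blur_r: float = 1.0 / 6.0
    d_max: float = 10.0
    sigma_max: float = 0.5
    min_track_displacements: int = 10
    rout_q_percent: float = 1.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.csmac_threshold <= 1):
            raise ValueError("csmac_threshold must be in (0, 1]")
        if self.csmac_max_clusters < 1:
            raise ValueError("csmac_max_clusters must be >= 1")
        if not (0 <= self.blur_r <= 0.25):
            raise ValueError("blur_r must be in [0, 1/4]")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.d_max <= 0 or self.sigma_max <= 0:
            raise ValueError("d_max and sigma_max must be positive")
        if self.min_track_displacements < 2:
            raise ValueError("min_track_displacements must be >= 2")
        if not (0 < self.rout_q_percent < 100):
            raise ValueError("rout_q_percent must be in (0, 100)")

    def segmentation_params(self, channel: str) -> SegmentationParams:
        if channel not in self.channels:
            raise KeyError(
                f"channel {channel!r} not defined in config "
                f"(known: {sorted(self.channels)})"
            )
        return self.channels[channel]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channels"] = {k: asdict(v) for k, v in self.channels.items()}
        return d

    def content_hash(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a RunConfig from YAML (missing keys take defaults)."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    channels = data.pop("channels", None)
    cfg = RunConfig(**data) if channels is None else RunConfig(
        channels={
            name: SegmentationParams(**(params or {}))
            for name, params in channels.items()
        },
        **data,
    )
    return cfg
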