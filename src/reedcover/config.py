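"""Run configuration: a single JSON-serialisable record driving every
pipeline stage, with field-level validation and unknown-key rejection."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # tiling
    tile_size: int = 32
    overlap_fraction: float = 0.5
    # dataset / split
    train_fraction: float = 0.7
    split_mode: str = "tile_shuffle"
    n_per_class: int = 20
    image_size: int = 64
    # model
    conv_channels: tuple[int, int] = (8, 16)
    kernel_size: int = 3
    pooling: str = "max"
    pool_size: int = 2
    # training
    epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 32
    # coverage
    threshold: float = 0.5
    risk_threshold: float = 0.6
    # scenes
    scene_size: int = 256
    target_coverage: float = 0.4
    # run
    seed: int = 0

    def __post_init__(self) -> None:
        self.conv_channels = tuple(self.conv_channels)
        checks = [
            (self.tile_size >= 4, "tile_size must be at least 4"),
            (0 <= self.overlap_fraction < 1, "overlap_fraction must be in [0, 1)"),
            (0 < self.train_fraction < 1, "train_fraction must be in (0, 1)"),
            (self.split_mode in ("tile_shuffle", "group_by_source"),
             f"unknown split_mode {self.split_mode!r}"),
            (self.n_per_class >= 1, "n_per_class must be positive"),
            (self.image_size >= self.tile_size, "image_size must be >= tile_size"),
            (self.pooling in ("max", "average"), f"unknown pooling {self.pooling!r}"),
            (self.epochs >= 1, "epochs must be positive"),
            (self.learning_rate >= 0, "learning_rate must be non-negative"),
            (self.batch_size >= 1, "batch_size must be positive"),
            (0 <= self.threshold <= 1, "threshold must be in [0, 1]"),
            (0 <= self.risk_threshold <= 1, "risk_threshold must be in [0, 1]"),
            (self.scene_size >= self.tile_size, "scene_size must be >= tile_size"),
            (0 <= self.target_coverage <= 1, "target_coverage must be in [0, 1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_channels"] = list(d["conv_channels"])
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def digest(self) -> str:
        """Stable hash of the effective configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
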