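"""Binary-labelled tile corpus and the shuffled 70/30 train/validation split.

Pure-class source images (reed fully present vs. reed absent) are cropped
into overlapping tiles; every tile inherits its source image's class label
and keeps provenance, so the split can optionally be made leakage-safe by
assigning whole source images to one side.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .tiler import extract_tiles, plan_tiles

__all__ = [
    "LABELS",
    "REED",
    "NON_REED",
    "TileRecord",
    "LabelledTileSet",
    "SplitAssignment",
    "build_dataset",
    "shuffle_split",
]

REED = "reed"
NON_REED = "non_reed"
LABELS = (NON_REED, REED)  # class index 0 = non_reed, 1 = reed


@dataclass(frozen=True)
class TileRecord:
    tile_id: str
    source_image_id: str
    image: np.ndarray  # tile_size x tile_size x 3 uint8
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")


class LabelledTileSet:
    """The corpus of labelled tiles, in deterministic build order."""

    def __init__(self, records: Sequence[TileRecord]):
        ids = [r.tile_id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("tile_ids must be unique")
        shapes = {r.image.shape for r in records}
        if len(shapes) > 1:
            raise ValueError(f"all tile rasters must share one shape, got {shapes}")
        self.records: tuple[TileRecord, ...] = tuple(records)
        self._by_id = {r.tile_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, tile_id: str) -> TileRecord:
        return self._by_id[tile_id]

    @property
    def tile_ids(self) -> list[str]:
        return [r.tile_id for r in self.records]

    def images(self, ids: Iterable[str] | None = None) -> np.ndarray:
        """Stack tiles (N x H x W x C uint8), in corpus order or in ``ids`` order."""
        recs = self.records if ids is None else [self._by_id[i] for i in ids]
        return np.stack([r.image for r in recs])

    def labels(self, ids: Iterable[str] | None = None) -> np.ndarray:
        """Class indices (0 = non_reed, 1 = reed), matching :meth:`images`."""
        recs = self.records if ids is None else [self._by_id[i] for i in ids]
        return np.array([LABELS.index(r.label) for r in recs], dtype=np.int64)

    def class_counts(self, ids: Iterable[str] | None = None) -> dict[str, int]:
        recs = self.records if ids is None else [self._by_id[i] for i in ids]
        return {lab: sum(r.label == lab for r in recs) for lab in LABELS}

    def write_manifest(self, path, split: "SplitAssignment | None" = None) -> None:
        """Write ``tile_id,source_image_id,label,split`` rows."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["tile_id", "source_image_id", "label", "split"])
            for r in self.records:
                part = ""
                if split is not None:
                    part = "train" if r.tile_id in split.train_ids else "val"
                writer.writerow([r.tile_id, r.source_image_id, r.label, part])


@dataclass(frozen=True)
class SplitAssignment:
    train_ids: frozenset[str]
    val_ids: frozenset[str]
    seed: int
    mode: str

    def __post_init__(self) -> None:
        if self.train_ids & self.val_ids:
            raise ValueError("train and validation partitions overlap")


def _promote_rgb(image: np.ndarray) -> np.ndarray:
    """Grayscale rasters become 3-channel so a single model path suffices."""
    image = np.asarray(image)
    if image.ndim == 2:
        image = np.repeat(image[:, :, None], 3, axis=2)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H x W or H x W x 3 raster, got shape {image.shape}")
    return image


def build_dataset(
    reed_images: Sequence[np.ndarray],
    nonreed_images: Sequence[np.ndarray],
    tile_size: int,
    overlap: float = 0.5,
) -> LabelledTileSet:
    """Tile every pure-class source image and label the crops.

    Source images of the reed class are photographed where reed cover is
    100 %, and the non-reed class where reed is absent, so every crop of an
    image carries that image's label.
    """
    if len(reed_images) == 0:
        raise ValueError("missing reed class: at least one reed source image required")
    if len(nonreed_images) == 0:
        raise ValueError("missing non_reed class: at least one non-reed source image required")
    records: list[TileRecord] = []
    for label, prefix, images in (
        (REED, "reed", reed_images),
        (NON_REED, "nonreed", nonreed_images),
    ):
        for i, img in enumerate(images):
            img = _promote_rgb(img)
            source_id = f"{prefix}_{i:03d}"
            plan = plan_tiles(img.shape[0], img.shape[1], tile_size, overlap)
            for k, tile in enumerate(extract_tiles(img, plan)):
                records.append(
                    TileRecord(f"{source_id}/t{k:04d}", source_id, tile, label)
                )
    return LabelledTileSet(records)


def train_size(n: int, train_fraction: float) -> int:
    """Round-half-up count of training tiles."""
    return int(math.floor(train_fraction * n + 0.5))


def shuffle_split(
    dataset: LabelledTileSet,
    train_fraction: float = 0.7,
    seed: int = 0,
    mode: str = "tile_shuffle",
) -> SplitAssignment:
    """Randomly split the corpus 70/30 (by default) into train and validation.

    ``mode="tile_shuffle"`` permutes individual tiles, matching the field
    protocol of shuffling all crops before splitting; note that with
    overlapping crops this leaks pixels between the partitions.
    ``mode="group_by_source"`` instead assigns whole source images to one
    side, so no two overlapping tiles straddle the split (the training
    partition size is then the closest achievable to the requested
    fraction in whole source images).
    """
    n = len(dataset)
    if n < 1:
        raise ValueError("dataset is empty")
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    ids = dataset.tile_ids
    n_train = train_size(n, train_fraction)
    if mode == "tile_shuffle":
        perm = rng.permutation(n)
        train = frozenset(ids[i] for i in perm[:n_train])
    elif mode == "group_by_source":
        sources: dict[str, list[str]] = {}
        for r in dataset.records:
            sources.setdefault(r.source_image_id, []).append(r.tile_id)
        order = rng.permutation(sorted(sources))
        picked: list[str] = []
        count = 0
        for src in order:
            if count >= n_train:
                break
            picked.extend(sources[src])
            count += len(sources[src])
        train = frozenset(picked)
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    val = frozenset(ids) - train
    return SplitAssignment(train_ids=train, val_ids=val, seed=seed, mode=mode)
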