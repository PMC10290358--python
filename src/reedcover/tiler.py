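"""Overlapping square tiling of rasters and probability stitching.

The classification unit of the pipeline is a fixed-size square crop
("tile").  Source rasters are truncated into tiles with a configurable
overlap fraction — 0.5 by default, i.e. the stride along each axis is half
the tile side — and per-tile reed probabilities are later averaged back
into a per-pixel field.

Coordinates are 0-based and windows are half-open: a window covers rows
``[row0, row0 + size)`` and columns ``[col0, col0 + size)``.  Windows are
ordered row-major.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "TileWindow",
    "TilePlan",
    "plan_tiles",
    "extract_tiles",
    "stitch_probabilities",
]


@dataclass(frozen=True)
class TileWindow:
    """A square pixel window inside a raster (0-based, half-open)."""

    row0: int
    col0: int
    size: int

    def __post_init__(self) -> None:
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError(f"window origin must be non-negative, got ({self.row0}, {self.col0})")
        if self.size < 1:
            raise ValueError(f"window size must be positive, got {self.size}")

    @property
    def rows(self) -> slice:
        return slice(self.row0, self.row0 + self.size)

    @property
    def cols(self) -> slice:
        return slice(self.col0, self.col0 + self.size)


@dataclass(frozen=True)
class TilePlan:
    """The full set of tile windows covering one raster, row-major."""

    image_height: int
    image_width: int
    tile_size: int
    overlap_fraction: float
    windows: tuple[TileWindow, ...]

    def __len__(self) -> int:
        return len(self.windows)

    def to_csv(self, path) -> None:
        """Write the plan as ``tile_id,row0,col0,size`` rows."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["tile_id", "row0", "col0", "size"])
            for i, w in enumerate(self.windows):
                writer.writerow([i, w.row0, w.col0, w.size])

    @staticmethod
    def axis_starts(dim: int, tile_size: int, stride: int) -> list[int]:
        """Window start positions along one axis under the shift-to-fit rule.

        Regular starts are 0, stride, 2*stride, ... as long as the window
        fits; if the last regular start does not place a window flush with
        the far edge, one extra start at ``dim - tile_size`` is appended so
        no margin is left uncovered.
        """
        starts = list(range(0, dim - tile_size + 1, stride))
        if starts[-1] != dim - tile_size:
            starts.append(dim - tile_size)
        return starts


def plan_tiles(
    height: int,
    width: int,
    tile_size: int,
    overlap_fraction: float = 0.5,
) -> TilePlan:
    """Plan square crops with the given overlap over an ``height x width`` raster.

    Parameters
    ----------
    height, width
        Raster dimensions in pixels; both must be >= ``tile_size``.
    tile_size
        Side of the square crop in pixels.
    overlap_fraction
        Shared proportion of adjacent windows along an axis, in [0, 1).
        The stride is ``round(tile_size * (1 - overlap_fraction))`` and must
        be at least one pixel.

    Returns
    -------
    TilePlan
        Row-major windows covering every pixel of the raster.
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    if tile_size < 1:
        raise ValueError(f"tile_size must be positive, got {tile_size}")
    if height < tile_size or width < tile_size:
        raise ValueError(
            f"raster {height}x{width} is too small to tile at size {tile_size}: "
            "both dimensions must be at least the tile size"
        )
    stride = round(tile_size * (1.0 - overlap_fraction))
    if stride < 1:
        raise ValueError(
            f"overlap {overlap_fraction} at tile size {tile_size} gives stride < 1"
        )
    row_starts = TilePlan.axis_starts(height, tile_size, stride)
    col_starts = TilePlan.axis_starts(width, tile_size, stride)
    windows = tuple(
        TileWindow(r, c, tile_size) for r in row_starts for c in col_starts
    )
    return TilePlan(height, width, tile_size, overlap_fraction, windows)


def extract_tiles(image: np.ndarray, plan: TilePlan) -> list[np.ndarray]:
    """Cut the planned crops out of ``image`` (H x W or H x W x C).

    Pixel values are copied unmodified; the returned list matches
    ``plan.windows`` order.
    """
    image = np.asarray(image)
    if image.shape[0] != plan.image_height or image.shape[1] != plan.image_width:
        raise ValueError(
            f"plan was built for {plan.image_height}x{plan.image_width} but the "
            f"image is {image.shape[0]}x{image.shape[1]}"
        )
    return [image[w.rows, w.cols].copy() for w in plan.windows]


def stitch_probabilities(
    plan: TilePlan,
    tile_probs: Sequence[float],
    height: int | None = None,
    width: int | None = None,
) -> np.ndarray:
    """Average per-tile reed probabilities into a per-pixel field.

    Every pixel's value is the arithmetic mean of the probabilities of all
    windows covering it; with 50 % overlap interior pixels are covered by
    four windows, edge pixels by fewer.
    """
    height = plan.image_height if height is None else height
    width = plan.image_width if width is None else width
    if height != plan.image_height or width != plan.image_width:
        raise ValueError("requested field dimensions do not match the plan")
    tile_probs = np.asarray(tile_probs, dtype=np.float64)
    if tile_probs.ndim != 1 or len(tile_probs) != len(plan.windows):
        raise ValueError(
            f"expected {len(plan.windows)} tile probabilities, got {len(tile_probs)}"
        )
    total = np.zeros((height, width), dtype=np.float64)
    count = np.zeros((height, width), dtype=np.int64)
    for w, p in zip(plan.windows, tile_probs):
        total[w.rows, w.cols] += p
        count[w.rows, w.cols] += 1
    if (count == 0).any():
        raise ValueError("plan does not cover every pixel")  # pragma: no cover
    return total / count
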