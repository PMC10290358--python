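"""Scene-level reed coverage mapping.

The trained tile classifier is slid over a full scene with the same
overlapping tiling used for training; per-tile reed probabilities are
averaged back into a per-pixel field, thresholded into a binary mask, and
summarised as the scene's coverage fraction.  An optional flag marks
scenes whose reed cover exceeds a heuristic biodiversity-risk threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .cnn import CNNClassifier
from .tiler import extract_tiles, plan_tiles, stitch_probabilities

__all__ = ["CoverageMap", "coverage_map", "risk_flag"]

#: Default coverage fraction above which a scene is flagged.  The value is
#: a heuristic placeholder — no field-validated criterion exists for when
#: reed expansion threatens open-water biodiversity.
DEFAULT_RISK_THRESHOLD = 0.6


@dataclass(frozen=True)
class CoverageMap:
    """Per-pixel reed probability, its thresholded mask, and the scalar fraction."""

    probability: np.ndarray  # H x W float in [0, 1]
    mask: np.ndarray  # H x W bool, True = reed
    coverage_fraction: float
    threshold: float
    tile_size: int

    def __post_init__(self) -> None:
        if self.probability.shape != self.mask.shape:
            raise ValueError("probability and mask dimensions differ")
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction must lie in [0, 1]")


def coverage_map(
    model: CNNClassifier,
    scene: np.ndarray,
    tile_size: int | None = None,
    overlap: float = 0.5,
    threshold: float = 0.5,
    mode: str = "mean",
) -> CoverageMap:
    """Classify a full scene and return its reed coverage map.

    Parameters
    ----------
    model
        Trained tile classifier; ``tile_size`` defaults to its spec.
    scene
        H x W x 3 raster, at least ``tile_size`` in both dimensions.
    threshold
        Mask cut on the per-pixel probability; ties (p == threshold)
        count as reed.
    mode
        ``"mean"`` stitches raw tile probabilities (smooth boundaries);
        ``"vote"`` hard-thresholds each tile at 0.5 first, so the field
        holds the local fraction of reed votes.
    """
    scene = np.asarray(scene)
    tile_size = model.spec.tile_size if tile_size is None else tile_size
    if scene.shape[0] < tile_size or scene.shape[1] < tile_size:
        raise ValueError(
            f"scene {scene.shape[0]}x{scene.shape[1]} is smaller than one tile; "
            f"minimum scene size is {tile_size}x{tile_size}"
        )
    if mode not in ("mean", "vote"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    plan = plan_tiles(scene.shape[0], scene.shape[1], tile_size, overlap)
    tiles = np.stack(extract_tiles(scene, plan))
    p_reed = model.predict_proba_array(tiles)[:, 1]
    if mode == "vote":
        p_reed = (p_reed >= 0.5).astype(np.float64)
    field = stitch_probabilities(plan, p_reed)
    mask = field >= threshold
    return CoverageMap(
        probability=field,
        mask=mask,
        coverage_fraction=float(mask.mean()),
        threshold=threshold,
        tile_size=tile_size,
    )


def risk_flag(
    cov: CoverageMap,
    risk_threshold: float = DEFAULT_RISK_THRESHOLD,
    scene_id: str = "",
) -> tuple[bool, dict]:
    """Flag a scene whose reed cover reaches the risk threshold (>= convention)."""
    if not 0.0 <= risk_threshold <= 1.0:
        raise ValueError(f"risk_threshold must be in [0, 1], got {risk_threshold}")
    flagged = cov.coverage_fraction >= risk_threshold
    report = {
        "scene": scene_id,
        "coverage_fraction": cov.coverage_fraction,
        "threshold": cov.threshold,
        "risk_threshold": risk_threshold,
        "flagged": flagged,
    }
    return flagged, report


def write_coverage_json(cov: CoverageMap, path, scene_id: str = "",
                        risk_threshold: float = DEFAULT_RISK_THRESHOLD) -> None:
    _, report = risk_flag(cov, risk_threshold, scene_id)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
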