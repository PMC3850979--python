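"""Pipeline configuration.

A single flat parameter set drives every stage; the shipped defaults are the
ones the method was designed around and are intended to be used unchanged
across an entire experiment (the robustness claim of the approach is that one
setting serves all frames).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Flat parameter set for the full detection pipeline.

    Background correction
    ---------------------
    tile_dim : int
        Edge length of the square tiles the frame is cut into, px.
    tile_overlap : int
        Overlap between neighbouring tiles, px; the lattice step is
        ``tile_dim - tile_overlap``.
    dbscan_eps, dbscan_min_pts :
        DBSCAN radius and minimum-neighbour count used to separate
        background-only tiles from tiles containing cells, applied to
        z-scored intensity-moment features.

    MSER segmentation
    -----------------
    mser_delta : int
        Threshold interval Δ over which region stability is measured.
    mser_min_size, mser_max_size : int
        Area bounds (px) for accepted extremal regions.
    mser_max_variation : float
        Upper bound on the relative area change over ±Δ.

    Clump splitting
    ---------------
    merge_max_eccentricity : float
        Fragments above this eccentricity are merge candidates, and a merge
        is only accepted when the merged object stays below it.
    merge_min_size, merge_max_size : int
        Area window (px) defining merge candidates.

    Object filtering
    ----------------
    filter_min_area : int
        Objects smaller than this are discarded as debris.
    filter_max_eccentricity : float
        Objects more elongated than this are discarded as line-like artifacts.

    Geometry
    --------
    pixel_size_um : float
        Microns per pixel; only used to convert counts to densities per mm².
        Camera/adapter dependent, so it must be calibrated per setup.
    """

    tile_dim: int = 30
    tile_overlap: int = 15
    dbscan_eps: float = 0.1
    dbscan_min_pts: int = 6
    mser_delta: int = 5
    mser_min_size: int = 30
    mser_max_size: int = 4000
    mser_max_variation: float = 1.0
    merge_max_eccentricity: float = 0.7
    merge_min_size: int = 30
    merge_max_size: int = 1000
    filter_min_area: int = 50
    filter_max_eccentricity: float = 0.99
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if self.tile_dim <= self.tile_overlap or self.tile_overlap < 0:
            raise ValueError("require tile_dim > tile_overlap >= 0")
        if not self.mser_min_size < self.mser_max_size:
            raise ValueError("require mser_min_size < mser_max_size")
        if not 0 < self.merge_max_eccentricity < self.filter_max_eccentricity <= 1:
            raise ValueError(
                "require 0 < merge_max_eccentricity < filter_max_eccentricity <= 1"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a flat key:value YAML file.

        Unknown keys raise; missing keys take the defaults.
        """
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
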