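"""Domain types and image/table I/O shared by all pipeline stages.

Coordinate convention, used package-wide: (row, col), 0-based, pixel centres
at integer coordinates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np


@dataclass
class RawImage:
    """An 8-bit grayscale frame plus its position in the acquisition series.

    ``fov_id`` identifies the field of view (camera position within a well);
    ``timepoint_index`` / ``time_hours`` place the frame in the time-lapse.
    """

    pixels: np.ndarray
    fov_id: str = "fov0"
    timepoint_index: int = 0
    time_hours: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("RawImage requires a 2-D pixel grid")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BackgroundEstimate:
    """Smooth, strictly positive illumination surface B(x) for one frame."""

    surface: np.ndarray

    def __post_init__(self) -> None:
        self.surface = np.asarray(self.surface, dtype=np.float64)
        if not np.all(self.surface > 0):
            raise ValueError("background surface must be strictly positive")


@dataclass
class CorrectedImage:
    """Ratio image I/B with halos clipped at the background level (1.0)."""

    pixels: np.ndarray
    clip_value: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)


@dataclass
class ForegroundMask:
    """Binary foreground mask; components are hole-filled by construction."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class CellObject:
    """Per-object measurements used for filtering and reporting.

    Eccentricity is that of the ellipse with identical normalized second
    central moments: 0 for a circle, approaching 1 for a line.
    """

    label: int
    area_px: int
    eccentricity: float
    centroid: tuple[float, float]
    touches_border: bool = False


CSV_FIELDS = ("label", "area_px", "eccentricity", "centroid_row", "centroid_col", "touches_border")


def read_image(path: str | Path, fov_id: str = "fov0", timepoint_index: int = 0,
               time_hours: float = 0.0) -> RawImage:
    """Read an 8-bit grayscale image file into a :class:`RawImage`.

    Multi-channel input is collapsed to grayscale by averaging channels.
    Images deeper than 8 bits are rejected: the MSER stage sweeps the 256
    discrete gray levels of an 8-bit image and is not defined for more.
    """
    arr = iio.imread(path)
    if arr.dtype != np.uint8:
        raise ValueError(
            f"{path}: bit depth {arr.dtype} not supported; the MSER stage "
            "requires 8-bit input — convert images to 8-bit first"
        )
    if arr.ndim == 3:
        arr = arr.astype(np.float64).mean(axis=2)
        arr = np.rint(arr).astype(np.uint8)
    elif arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    return RawImage(arr, fov_id=fov_id, timepoint_index=timepoint_index,
                    time_hours=time_hours)


def write_mask(mask: ForegroundMask | np.ndarray, path: str | Path) -> None:
    """Write a mask as PNG: binary masks as 8-bit 0/255, labeled as 16-bit.

    16-bit output keeps label identity for frames with far more than 255
    objects (dense late-experiment frames exceed 1000 cells).
    """
    arr = mask.mask if isinstance(mask, ForegroundMask) else np.asarray(mask)
    if arr.dtype == bool:
        out = np.where(arr, 255, 0).astype(np.uint8)
    else:
        if arr.min() < 0 or arr.max() > np.iinfo(np.uint16).max:
            raise ValueError("labels out of uint16 range")
        out = arr.astype(np.uint16)
    iio.imwrite(path, out)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG back: uint8 → boolean, uint16 → integer labels."""
    arr = iio.imread(path)
    if arr.dtype == np.uint8:
        return arr > 0
    return arr.astype(np.int64)


def write_objects_csv(objects: list[CellObject], path: str | Path) -> None:
    """Write one CSV row per object (header always present)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_FIELDS)
        for obj in objects:
            writer.writerow([
                obj.label, obj.area_px, f"{obj.eccentricity:.9g}",
                f"{obj.centroid[0]:.9g}", f"{obj.centroid[1]:.9g}",
                int(obj.touches_border),
            ])


def read_objects_csv(path: str | Path) -> list[CellObject]:
    objects = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            objects.append(CellObject(
                label=int(row["label"]),
                area_px=int(row["area_px"]),
                eccentricity=float(row["eccentricity"]),
                centroid=(float(row["centroid_row"]), float(row["centroid_col"])),
                touches_border=bool(int(row["touches_border"])),
            ))
    return objects
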