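"""Synthetic out-of-focus bright-field frames with exact ground truth.

The generator emulates the phenomenology of deliberately defocused
bright-field acquisition rather than its optics: a bright, smoothly varying
illumination surface; evenly dark ellipsoid cell bodies; a bright halo ring
around every cell; slightly brighter interfaces where cells touch; small
dark debris specks below the cell-size filter; additive sensor noise; and a
Gaussian edge blur standing in for defocus. Every frame comes with the
pre-noise ellipse label grid as ground truth, so detection, splitting and
filtering can each be scored exactly.

Time-lapse series follow the canonical culture trajectory — a slow lag
phase, clean exponential growth with a stated doubling time, and a plateau
when the well saturates — with per-field-of-view Poisson variation around
the expected counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import RawImage
from .objects import measure_objects


@dataclass
class SceneSpec:
    """Parameters of one rendered frame.

    Intensity is organized multiplicatively: the illumination surface B(x)
    carries the absolute 8-bit scale while cells, halos and debris are
    ratios relative to local background (interior ≈ 0.4–0.7, halo > 1).
    Defaults describe a moderately crowded field of small round cells
    (radius ≈ 6.5 px, i.e. ~130 px² bodies) of which a fifth sit in touching
    clusters of 2–5.
    """

    image_shape: tuple[int, int] = (768, 1024)
    illumination: str = "planar"            # "flat" | "planar" | "quadratic"
    illumination_range: tuple[float, float] = (110.0, 170.0)
    n_cells: int = 400
    radius_mean: float = 8.0
    radius_sd: float = 1.5
    radius_min: float = 5.0
    axis_ratio_range: tuple[float, float] = (0.8, 1.0)
    interior_ratio_range: tuple[float, float] = (0.4, 0.7)
    halo_width: float = 2.0
    halo_ratio: float = 1.15
    interface_ratio: float = 0.85
    cluster_fraction: float = 0.2
    cluster_size_range: tuple[int, int] = (2, 5)
    cluster_overlap: float = 0.3            # max overlap as fraction of the smaller radius
    min_gap: float = 5.0                    # clearance between non-cluster cells
    debris_count: int = 15
    debris_radius_range: tuple[float, float] = (1.2, 2.6)
    debris_ratio_range: tuple[float, float] = (0.5, 0.75)
    noise_sd: float = 2.0
    blur_sigma: float = 1.0
    seed: int = 0


@dataclass
class GroundTruth:
    """Exact per-frame truth: cell label grid, records, and debris mask."""

    labels: np.ndarray
    cells: pd.DataFrame        # label, centroid_row, centroid_col, area_px, eccentricity
    debris_mask: np.ndarray
    background: np.ndarray     # the true illumination surface B(x)
    foreground_ratio: np.ndarray  # the true pre-noise ratio field F(x)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _illumination(spec: SceneSpec) -> np.ndarray:
    h, w = spec.image_shape
    lo, hi = spec.illumination_range
    if spec.illumination == "flat":
        return np.full((h, w), (lo + hi) / 2.0)
    cols = np.linspace(0.0, 1.0, w)[None, :]
    rows = np.linspace(0.0, 1.0, h)[:, None]
    if spec.illumination == "planar":
        return lo + (hi - lo) * (cols * np.ones((h, 1)))
    if spec.illumination == "quadratic":
        r2 = (rows - 0.5) ** 2 + (cols - 0.5) ** 2
        return hi - (hi - lo) * (r2 / 0.5)
    raise ValueError(f"unknown illumination kind {spec.illumination!r}")


@dataclass(eq=False)
class _Cell:
    row: float
    col: float
    a: float     # semi-major axis, px
    b: float     # semi-minor axis, px
    theta: float
    ratio: float

    @property
    def reach(self) -> float:
        return self.a


def _draw_cell(rng: np.random.Generator, spec: SceneSpec,
               row: float, col: float) -> _Cell:
    r = max(rng.normal(spec.radius_mean, spec.radius_sd), spec.radius_min)
    q = rng.uniform(*spec.axis_ratio_range)
    # preserve area: a*b = r^2
    a, b = r / math.sqrt(q), r * math.sqrt(q)
    return _Cell(row, col, a, b, rng.uniform(0, math.pi),
                 rng.uniform(*spec.interior_ratio_range))


def _place_cells(rng: np.random.Generator, spec: SceneSpec) -> list[list[_Cell]]:
    """Place cells as singletons and touching clusters; returns groups."""
    h, w = spec.image_shape
    margin = spec.radius_mean + 3 * spec.radius_sd + spec.halo_width + 3
    placed: list[_Cell] = []
    groups: list[list[_Cell]] = []

    def clear_of_others(cell: _Cell, exempt: list[_Cell], gap: float) -> bool:
        return all(math.hypot(cell.row - o.row, cell.col - o.col)
                   >= cell.reach + o.reach + gap
                   for o in placed if o not in exempt)

    n_target = spec.n_cells
    n_clustered = int(round(spec.cluster_fraction * n_target))
    cluster_sizes: list[int] = []
    while sum(cluster_sizes) < n_clustered:
        k = int(rng.integers(spec.cluster_size_range[0],
                             spec.cluster_size_range[1] + 1))
        cluster_sizes.append(min(k, n_clustered - sum(cluster_sizes) + 1))
    n_single = n_target - sum(cluster_sizes)

    max_tries = 400 * max(n_target, 1)
    tries = 0

    def random_pos() -> tuple[float, float]:
        return (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))

    for k in cluster_sizes:
        while True:
            tries += 1
            if tries > max_tries:
                raise RuntimeError("cell placement infeasible: density too high")
            seed_cell = _draw_cell(rng, spec, *random_pos())
            if clear_of_others(seed_cell, [], spec.min_gap):
                break
        group = [seed_cell]
        placed.append(seed_cell)
        while len(group) < k:
            tries += 1
            if tries > max_tries:
                raise RuntimeError("cell placement infeasible: density too high")
            anchor = group[int(rng.integers(len(group)))]
            cand = _draw_cell(rng, spec, anchor.row, anchor.col)
            overlap = rng.uniform(0.2, 1.0) * spec.cluster_overlap \
                * min(anchor.reach, cand.reach)
            d = anchor.reach + cand.reach - overlap
            ang = rng.uniform(0, 2 * math.pi)
            cand.row = anchor.row + d * math.sin(ang)
            cand.col = anchor.col + d * math.cos(ang)
            if not (margin <= cand.row <= h - margin
                    and margin <= cand.col <= w - margin):
                continue
            # rigid-body packing: a cell may overlap (by up to
            # cluster_overlap of the smaller radius) only its anchor; with
            # every other member it can touch but not interpenetrate
            too_deep = any(
                math.hypot(cand.row - o.row, cand.col - o.col)
                < (cand.reach + o.reach) * 0.98
                for o in group if o is not anchor)
            if not too_deep and clear_of_others(cand, group, spec.min_gap):
                group.append(cand)
                placed.append(cand)
        groups.append(group)

    for _ in range(n_single):
        while True:
            tries += 1
            if tries > max_tries:
                raise RuntimeError("cell placement infeasible: density too high")
            cand = _draw_cell(rng, spec, *random_pos())
            if clear_of_others(cand, [], spec.min_gap):
                placed.append(cand)
                groups.append([cand])
                break
    return groups


def generate_frame(spec: SceneSpec) -> tuple[RawImage, GroundTruth]:
    """Render one frame and its exact ground truth.

    Deterministic for a fixed spec (seed included): running twice yields
    byte-identical pixels.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    bg = _illumination(spec)

    groups = _place_cells(rng, spec) if spec.n_cells > 0 else []
    cells = [c for g in groups for c in g]

    ratio = np.ones((h, w))
    labels = np.zeros((h, w), dtype=np.int32)
    # normalized elliptical distance per pixel; overlaps go to the nearer cell
    rho_best = np.full((h, w), np.inf)
    halo_zone = np.zeros((h, w), dtype=bool)

    for idx, cell in enumerate(cells, start=1):
        reach = cell.a + spec.halo_width + 2
        r0, r1 = max(int(cell.row - reach), 0), min(int(cell.row + reach) + 2, h)
        c0, c1 = max(int(cell.col - reach), 0), min(int(cell.col + reach) + 2, w)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        dr, dc = rr - cell.row, cc - cell.col
        u = dr * math.sin(cell.theta) + dc * math.cos(cell.theta)
        v = -dr * math.cos(cell.theta) + dc * math.sin(cell.theta)
        rho = np.sqrt((u / cell.a) ** 2 + (v / cell.b) ** 2)
        inside = rho <= 1.0
        win = (slice(r0, r1), slice(c0, c1))
        take = inside & (rho < rho_best[win])
        labels[win][take] = idx
        rho_best[win] = np.where(take, rho, rho_best[win])
        halo = (rho > 1.0) & (rho <= 1.0 + spec.halo_width / cell.b)
        halo_zone[win] |= halo

    # interior intensities follow the final label assignment
    for idx, cell in enumerate(cells, start=1):
        ratio[labels == idx] = cell.ratio
    halo_zone &= labels == 0
    ratio[halo_zone] = spec.halo_ratio

    # touching-cell interfaces are slightly brighter than the cell interiors
    if cells:
        interface = np.zeros((h, w), dtype=bool)
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
            a = labels[max(dr, 0):h - max(-dr, 0) or h, max(dc, 0):w - max(-dc, 0) or w]
            b = labels[max(-dr, 0):h - max(dr, 0) or h, max(-dc, 0):w - max(dc, 0) or w]
            diff = (a > 0) & (b > 0) & (a != b)
            interface[max(dr, 0):h - max(-dr, 0) or h,
                      max(dc, 0):w - max(-dc, 0) or w] |= diff
            interface[max(-dr, 0):h - max(dr, 0) or h,
                      max(-dc, 0):w - max(dc, 0) or w] |= diff
        ratio[interface] = spec.interface_ratio

    # debris: dark specks well below the cell-area filter
    debris_mask = np.zeros((h, w), dtype=bool)
    for _ in range(spec.debris_count):
        dr_ = rng.uniform(*spec.debris_radius_range)
        prow, pcol = rng.uniform(0, h), rng.uniform(0, w)
        val = rng.uniform(*spec.debris_ratio_range)
        r0, r1 = max(int(prow - dr_ - 1), 0), min(int(prow + dr_) + 2, h)
        c0, c1 = max(int(pcol - dr_ - 1), 0), min(int(pcol + dr_) + 2, w)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        spot = ((rr - prow) ** 2 + (cc - pcol) ** 2) <= dr_ ** 2
        win = (slice(r0, r1), slice(c0, c1))
        spot &= labels[win] == 0
        ratio[win][spot] = val
        debris_mask[win] |= spot

    blurred = ndimage.gaussian_filter(ratio, spec.blur_sigma) if spec.blur_sigma > 0 else ratio
    img = blurred * bg + rng.normal(0.0, spec.noise_sd, size=(h, w))
    img8 = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    records = measure_objects(labels)
    cells_df = pd.DataFrame({
        "label": [o.label for o in records],
        "centroid_row": [o.centroid[0] for o in records],
        "centroid_col": [o.centroid[1] for o in records],
        "area_px": [o.area_px for o in records],
        "eccentricity": [o.eccentricity for o in records],
    })
    truth = GroundTruth(labels, cells_df, debris_mask, bg, ratio)
    return RawImage(img8), truth


@dataclass
class GrowthSpec:
    """Expected-count trajectory: lag → exponential → plateau.

    During the lag the population grows slowly (doubling time
    ``lag_doubling_hours``); after ``lag_hours`` it grows exponentially with
    ``exp_doubling_hours`` until the expected count reaches
    ``plateau_count``, where it stays.
    """

    n0: float = 50.0
    lag_hours: float = 48.0
    lag_doubling_hours: float = 40.0
    exp_doubling_hours: float = 10.0
    plateau_count: float = 2000.0


def expected_counts(growth: GrowthSpec, time_hours: np.ndarray) -> np.ndarray:
    t = np.asarray(time_hours, dtype=float)
    n_lag_end = growth.n0 * 2 ** (growth.lag_hours / growth.lag_doubling_hours)
    n = np.where(
        t < growth.lag_hours,
        growth.n0 * 2 ** (t / growth.lag_doubling_hours),
        n_lag_end * 2 ** ((t - growth.lag_hours) / growth.exp_doubling_hours),
    )
    return np.minimum(n, growth.plateau_count)


def generate_timelapse(growth: GrowthSpec, duration_hours: float = 144.0,
                       interval_minutes: float = 2.3, n_fov: int = 66,
                       seed: int = 0, poisson: bool = True) -> pd.DataFrame:
    """Per-(fov, timepoint) realized cell counts for a growing culture.

    Counts are Poisson draws around each field of view's expected count
    (``poisson=False`` gives the rounded expectation exactly). Returns a
    table with columns (fov, timepoint, time_hours, n_cells).
    """
    if interval_minutes <= 0:
        raise ValueError("interval must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_hours + 1e-9, interval_minutes / 60.0)
    expected = expected_counts(growth, times)
    rows = []
    for fov in range(n_fov):
        counts = (rng.poisson(expected) if poisson
                  else np.rint(expected).astype(int))
        rows.append(pd.DataFrame({
            "fov": fov, "timepoint": np.arange(len(times)),
            "time_hours": times, "n_cells": counts}))
    return pd.concat(rows, ignore_index=True)


def render_timelapse_frames(scene: SceneSpec, counts: pd.DataFrame,
                            ) -> "list[tuple[RawImage, GroundTruth]]":
    """Render a frame for every (fov, timepoint) row of a counts table.

    Each frame reuses the scene parameters but substitutes the row's cell
    count and derives a per-frame seed from the scene seed and the row's
    (fov, timepoint), so the series is reproducible row by row.
    """
    import dataclasses as _dc
    frames = []
    for row in counts.itertuples():
        frame_spec = _dc.replace(
            scene, n_cells=int(row.n_cells),
            seed=(scene.seed * 1_000_003 + int(row.fov) * 9973
                  + int(row.timepoint)) % (2 ** 31))
        img, truth = generate_frame(frame_spec)
        img.fov_id = f"fov{int(row.fov)}"
        img.timepoint_index = int(row.timepoint)
        img.time_hours = float(row.time_hours)
        frames.append((img, truth))
    return frames
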