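"""Machine-learning illumination correction for bright-field frames.

Bright-field illumination is inhomogeneous across the field of view and
drifts over a long time-lapse. Rather than assuming a parametric vignetting
model, the frame is cut into overlapping tiles, each tile is summarised by
the first four standardized moments of its intensity histogram, and
density-based clustering separates pure-background tiles from tiles that
contain cells. The mean intensities of the background tiles then act as
scattered seed points through which a smooth surface B(x) is inter- and
extrapolated. Dividing the raw frame by B(x) yields a ratio image in which
pure background sits at 1.0; the bright halo around each defocused cell is
removed by clipping all ratios above 1.0 back to 1.0.

Each frame is corrected independently — no temporal smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RBFInterpolator, RegularGridInterpolator
from sklearn.cluster import DBSCAN

from .io import BackgroundEstimate, CorrectedImage, RawImage


@dataclass
class TileGrid:
    """Overlapping square tiles on a regular lattice covering the frame.

    ``tiles`` holds (row_origin, col_origin, height, width); boundary tiles
    are clipped to the image extent so every pixel is covered.
    """

    image_shape: tuple[int, int]
    tile_dim: int
    overlap: int
    tiles: list[tuple[int, int, int, int]]
    features: np.ndarray | None = None       # raw per-tile moments, (n, 4)
    features_scaled: np.ndarray | None = None  # z-scored across tiles
    is_background: np.ndarray | None = None  # per-tile boolean

    def centers(self) -> np.ndarray:
        """Tile centres in (row, col) pixel coordinates."""
        return np.array([(r + h / 2 - 0.5, c + w / 2 - 0.5)
                         for r, c, h, w in self.tiles])


def tile_image(image: RawImage | np.ndarray, tile_dim: int = 30,
               overlap: int = 15) -> TileGrid:
    """Lay overlapping tiles on a regular lattice with step tile_dim − overlap.

    Lattice origins run from 0 in steps of the lattice spacing; an extra
    final origin is added when the last regular tile does not reach the image
    edge, and boundary tiles are clipped to the frame.
    """
    pixels = image.pixels if isinstance(image, RawImage) else np.asarray(image)
    h, w = pixels.shape
    if tile_dim <= overlap or overlap < 0:
        raise ValueError("require tile_dim > overlap >= 0")
    if h < tile_dim or w < tile_dim:
        raise ValueError(
            f"image {h}x{w} smaller than one {tile_dim}x{tile_dim} tile")
    step = tile_dim - overlap

    def origins(extent: int) -> list[int]:
        out = list(range(0, max(extent - tile_dim, 0) + 1, step))
        if out[-1] + tile_dim < extent:
            out.append(extent - tile_dim)
        return out

    tiles = [(r, c, min(tile_dim, h - r), min(tile_dim, w - c))
             for r in origins(h) for c in origins(w)]
    return TileGrid((h, w), tile_dim, overlap, tiles)


def tile_features(image: RawImage | np.ndarray, grid: TileGrid) -> TileGrid:
    """Attach per-tile intensity-moment features, z-scored across tiles.

    Features are the first four standardized moments (mean, variance,
    skewness, excess kurtosis) of each tile's pixel intensities. Constant
    tiles get skewness = kurtosis = 0. Z-scoring puts the features on a
    common scale so the fixed DBSCAN radius is meaningful.
    """
    pixels = (image.pixels if isinstance(image, RawImage)
              else np.asarray(image)).astype(np.float64)
    feats = np.empty((len(grid.tiles), 4))
    for i, (r, c, th, tw) in enumerate(grid.tiles):
        v = pixels[r:r + th, c:c + tw].ravel()
        m = v.mean()
        var = v.var()
        if var == 0:
            feats[i] = (m, 0.0, 0.0, 0.0)
        else:
            z = (v - m) / np.sqrt(var)
            feats[i] = (m, var, np.mean(z ** 3), np.mean(z ** 4) - 3.0)
    grid.features = feats
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    grid.features_scaled = (feats - feats.mean(axis=0)) / sd
    return grid


def classify_tiles(grid: TileGrid, eps: float = 0.1, min_pts: int = 6,
                   min_background_fraction: float = 0.25) -> TileGrid:
    """Split tiles into background vs foreground-mixture by DBSCAN.

    The most-populated cluster is taken as background — background dominates
    the tile count at every cell density the method targets. Noise points and
    all smaller clusters are conservatively treated as foreground-mixture.

    ``eps`` is treated as the starting radius: when the densest cluster
    holds less than ``min_background_fraction`` of the tiles — which cannot
    be the dominant background — the radius is doubled and clustering is
    repeated (a few times at most). This keeps the small published radius
    effective on crowded frames while remaining robust on nearly featureless
    ones, where z-scoring stretches pure sensor noise to unit scale.
    """
    if grid.features_scaled is None:
        raise ValueError("call tile_features first")
    n = len(grid.tiles)
    best = None
    for attempt in range(7):
        radius = eps * 2 ** attempt
        labels = DBSCAN(eps=radius, min_samples=min_pts).fit_predict(
            grid.features_scaled)
        cluster_ids, counts = np.unique(labels[labels >= 0], return_counts=True)
        if cluster_ids.size:
            bg_cluster = cluster_ids[np.argmax(counts)]
            best = labels == bg_cluster
            if counts.max() >= min_background_fraction * n:
                break
    if best is None:
        raise RuntimeError(
            "DBSCAN found no cluster: no background tiles identified, "
            "background estimation impossible (check eps/min_pts or tile size)")
    grid.is_background = best
    return grid


def estimate_background(image: RawImage | np.ndarray, grid: TileGrid,
                        *, _eval_step: int = 4) -> BackgroundEstimate:
    """Interpolate a smooth illumination surface through background tiles.

    Each background tile contributes one seed point: its mean intensity
    anchored at the tile centre. A thin-plate-spline radial basis function
    interpolant (with k-nearest-neighbour locality for speed) is evaluated on
    a coarse pixel lattice and bilinearly upsampled — the illumination field
    is smooth by assumption, so the decimation is lossless in practice. The
    surface is floored at 1 intensity unit so the division is always safe.
    """
    pixels = (image.pixels if isinstance(image, RawImage)
              else np.asarray(image)).astype(np.float64)
    if grid.is_background is None:
        raise ValueError("call classify_tiles first")
    bg_idx = np.flatnonzero(grid.is_background)
    if bg_idx.size < 3:
        raise RuntimeError(
            f"only {bg_idx.size} background tiles — need >= 3 seed points")
    centers = grid.centers()[bg_idx]
    means = np.array([pixels[r:r + th, c:c + tw].mean()
                      for r, c, th, tw in (grid.tiles[i] for i in bg_idx)])
    if np.linalg.matrix_rank(
            np.c_[centers, np.ones(len(centers))], tol=1e-9) < 3:
        raise RuntimeError("background seed points are collinear")

    h, w = pixels.shape
    # the surface has few degrees of freedom; cap the seed count so the
    # global solve stays cheap on dense tile grids
    if len(centers) > 1200:
        keep = np.linspace(0, len(centers) - 1, 1200).astype(int)
        centers, means = centers[keep], means[keep]
    # degree-2 polynomial tail: beyond the seed hull the thin-plate kernel
    # itself overshoots, while typical vignetting is locally quadratic
    rbf = RBFInterpolator(centers, means, kernel="thin_plate_spline",
                          smoothing=1.0, degree=2)

    rows = np.unique(np.r_[np.arange(0, h, _eval_step), h - 1])
    cols = np.unique(np.r_[np.arange(0, w, _eval_step), w - 1])
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    coarse = rbf(np.c_[rr.ravel(), cc.ravel()]).reshape(rr.shape)
    interp = RegularGridInterpolator((rows, cols), coarse, method="linear")
    fr, fc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    surface = interp(np.c_[fr.ravel(), fc.ravel()]).reshape(h, w)
    return BackgroundEstimate(np.maximum(surface, 1.0))


def correct_image(image: RawImage | np.ndarray,
                  background: BackgroundEstimate) -> CorrectedImage:
    """Divide the frame by its background and clip halos to 1.0.

    Pixels brighter than the local background (the defocus halo) are set to
    the background-equivalent ratio 1.0; all other ratios pass unchanged, so
    cell interiors end up as values well below 1.
    """
    pixels = (image.pixels if isinstance(image, RawImage)
              else np.asarray(image)).astype(np.float64)
    if pixels.shape != background.surface.shape:
        raise ValueError("image and background shapes differ")
    ratio = pixels / background.surface
    return CorrectedImage(np.minimum(ratio, 1.0))


def correct_frame(image: RawImage | np.ndarray, tile_dim: int = 30,
                  overlap: int = 15, eps: float = 0.1,
                  min_pts: int = 6) -> tuple[CorrectedImage, BackgroundEstimate]:
    """Convenience wrapper: tile → features → classify → estimate → divide."""
    grid = tile_image(image, tile_dim, overlap)
    grid = tile_features(image, grid)
    grid = classify_tiles(grid, eps, min_pts)
    bg = estimate_background(image, grid)
    return correct_image(image, bg), bg
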