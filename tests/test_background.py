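"""Tile lattice, tile features, tile classification and surface recovery."""

import numpy as np
import pytest

from brightcell.background import (classify_tiles, correct_frame,
                                   correct_image, estimate_background,
                                   tile_features, tile_image)
from brightcell.io import BackgroundEstimate, RawImage
from brightcell.synthetic import SceneSpec, generate_frame


@pytest.mark.parametrize("shape,tile,overlap,expected", [
    ((60, 60), 30, 15, 9),     # 3x3 lattice
    ((30, 30), 30, 15, 1),     # degenerate single tile
    ((45, 60), 30, 15, 6),     # 2x3
])
def test_tile_lattice_counts(shape, tile, overlap, expected):
    grid = tile_image(np.zeros(shape, dtype=np.uint8), tile, overlap)
    assert len(grid.tiles) == expected


def test_tile_lattice_matches_enumeration_and_covers_frame():
    shape = (1040, 1388)
    grid = tile_image(np.zeros(shape, dtype=np.uint8), 30, 15)

    def origins(extent):
        out = list(range(0, extent - 30 + 1, 15))
        if out[-1] + 30 < extent:
            out.append(extent - 30)
        return out

    assert len(grid.tiles) == len(origins(shape[0])) * len(origins(shape[1]))
    covered = np.zeros(shape, dtype=bool)
    for r, c, th, tw in grid.tiles:
        covered[r:r + th, c:c + tw] = True
    assert covered.all()


def test_image_smaller_than_tile_rejected():
    with pytest.raises(ValueError, match="smaller"):
        tile_image(np.zeros((20, 20), dtype=np.uint8), 30, 15)


def test_tile_features_constant_and_bimodal():
    img = np.full((30, 30), 100, dtype=np.uint8)
    grid = tile_features(img, tile_image(img, 30, 15))
    assert grid.features[0] == pytest.approx([100.0, 0.0, 0.0, 0.0])

    half = np.zeros((30, 60), dtype=np.uint8)
    half[:, 30:] = 255
    grid = tile_features(half, tile_image(half, 30, 15))
    # middle tile straddles the step: half 0s, half 255s
    mid = [i for i, (r, c, _, _) in enumerate(grid.tiles) if c == 15][0]
    v = half[:, 15:45].astype(float)
    assert grid.features[mid][0] == pytest.approx(127.5)
    assert grid.features[mid][1] == pytest.approx(v.var())


def test_cell_tiles_have_higher_variance_than_background_tiles():
    img, truth = generate_frame(SceneSpec(image_shape=(256, 256), n_cells=12,
                                          debris_count=0, seed=4))
    grid = tile_features(img.pixels, tile_image(img.pixels, 30, 15))
    cell_cover = truth.labels > 0
    cell_vars, bg_vars = [], []
    for (r, c, th, tw), feat in zip(grid.tiles, grid.features):
        frac = cell_cover[r:r + th, c:c + tw].mean()
        (cell_vars if frac > 0.2 else bg_vars if frac == 0 else []).append(feat[1])
    assert min(cell_vars) > np.median(bg_vars)


def test_classify_tiles_marks_true_background_tiles():
    from scipy import ndimage

    img, truth = generate_frame(SceneSpec(image_shape=(512, 512), n_cells=40,
                                          seed=5))
    grid = classify_tiles(tile_features(img.pixels, tile_image(img.pixels, 30, 15)))
    # foreground influence includes the halo ring the generator draws
    cell_cover = ndimage.binary_dilation(truth.labels > 0, iterations=3)
    pure = np.array([cell_cover[r:r + th, c:c + tw].sum() == 0
                     for r, c, th, tw in grid.tiles])
    # nearly all genuinely pure tiles should be classified background
    assert grid.is_background[pure].mean() >= 0.9
    # and tiles called background should rarely contain cells
    assert pure[grid.is_background].mean() >= 0.9


def test_classify_constructed_feature_populations():
    """The most-populated DBSCAN cluster becomes the background class."""
    rng = np.random.default_rng(0)
    grid = tile_image(np.zeros((60, 120), dtype=np.uint8), 30, 15)
    grid = tile_features(np.zeros((60, 120), dtype=np.uint8), grid)
    n = len(grid.tiles)
    n_bg = int(0.8 * n)
    feats = np.vstack([rng.normal(0, 0.01, (n_bg, 4)),
                       rng.normal(3, 0.01, (n - n_bg, 4))])
    grid.features_scaled = feats  # pre-scaled constructed populations
    grid = classify_tiles(grid, eps=0.5, min_pts=3)
    assert grid.is_background[:n_bg].all()
    assert not grid.is_background[n_bg:].any()


def test_all_identical_tiles_form_one_background_cluster():
    img = np.full((60, 60), 120, dtype=np.uint8)
    grid = classify_tiles(tile_features(img, tile_image(img, 30, 15)))
    assert grid.is_background.all()


def test_estimate_background_constant_and_planar():
    img = np.full((60, 60), 140, dtype=np.uint8)
    grid = classify_tiles(tile_features(img, tile_image(img, 30, 15)))
    bg = estimate_background(img, grid)
    assert bg.surface == pytest.approx(np.full((60, 60), 140.0), rel=1e-3)

    # seeds on a plane reproduce the plane
    ramp = np.clip(np.rint(80 + np.arange(240) / 239 * 80), 0, 255).astype(np.uint8)
    plane = np.tile(ramp, (120, 1))
    grid = classify_tiles(tile_features(plane, tile_image(plane, 30, 15)))
    bg = estimate_background(plane, grid)
    assert np.abs(bg.surface - plane).max() <= 1.5  # within quantization


def test_correct_image_divides_and_clips():
    img = np.full((8, 8), 100, dtype=np.uint8)
    img[0, 0] = 200   # halo pixel brighter than background
    img[1, 1] = 50
    bg = BackgroundEstimate(np.full((8, 8), 100.0))
    out = correct_image(img, bg)
    assert out.pixels[0, 0] == 1.0
    assert out.pixels[1, 1] == pytest.approx(0.5)
    assert out.pixels[2, 2] == 1.0
    assert out.pixels.max() <= 1.0 and out.pixels.min() > 0


def test_pure_background_frame_corrects_to_unity():
    """Systematic correction error on a cell-free frame stays within 2%.

    Noise-free frames are checked pixelwise; on a noisy frame the sensor
    noise itself exceeds any tight pixel band, so the smoothed field is
    what must sit at 1.0.
    """
    from scipy import ndimage

    img, _ = generate_frame(SceneSpec(image_shape=(256, 256), n_cells=0,
                                      debris_count=0, noise_sd=0.0, seed=6))
    corrected, _ = correct_frame(img)
    assert np.abs(corrected.pixels - 1.0).max() <= 0.02

    img, _ = generate_frame(SceneSpec(image_shape=(256, 256), n_cells=0,
                                      debris_count=0, seed=6))
    corrected, _ = correct_frame(img)
    smooth = ndimage.uniform_filter(corrected.pixels, size=9)
    assert np.abs(smooth - 1.0).max() <= 0.02


def test_gain_invariance_of_correction():
    """Scaling the raw frame by a gain leaves the ratio image unchanged."""
    img, _ = generate_frame(SceneSpec(image_shape=(256, 256), n_cells=10,
                                      illumination_range=(90.0, 120.0),
                                      debris_count=0, seed=7))
    corr1, _ = correct_frame(img)
    scaled = RawImage(np.clip(np.rint(img.pixels * 1.5), 0, 255).astype(np.uint8))
    corr2, _ = correct_frame(scaled)
    # identical up to the 8-bit quantization both frames passed through
    assert np.abs(corr1.pixels - corr2.pixels).mean() < 0.01


def test_multiplicative_field_recovery():
    """Cells at <=20% cover do not bias the recovered planar field."""
    from scipy import ndimage

    img, truth = generate_frame(SceneSpec(
        image_shape=(256, 256), n_cells=25, debris_count=0,
        illumination="planar", illumination_range=(80.0, 160.0), seed=8))
    _, bg = correct_frame(img)
    pure = ndimage.binary_erosion(truth.labels == 0, iterations=4)
    rel = np.abs(bg.surface - truth.background) / truth.background
    assert rel[pure].max() <= 0.02
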