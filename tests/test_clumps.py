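"""Distance-transform seeding, watershed splitting, and merge repair."""

import numpy as np
import pytest
from skimage.measure import label as cc_label, regionprops

from brightcell.clumps import (InterfaceModel, find_seeds, fit_interface_model,
                               merge_fragments, split_clumps, watershed_split)
from brightcell.config import PipelineConfig

from conftest import disk_mask


def two_disk_dumbbell(shape=(64, 80), r=10, d=16):
    c1, c2 = (32, 28), (32, 28 + d)
    return disk_mask(shape, c1, r) | disk_mask(shape, c2, r), c1, c2


def test_single_disk_yields_single_central_seed():
    mask = disk_mask((64, 64), (32, 32), 12)
    seeds = find_seeds(mask)
    lab = cc_label(seeds, connectivity=2)
    assert lab.max() == 1
    srow, scol = np.argwhere(seeds).mean(axis=0)
    assert (srow, scol) == pytest.approx((32, 32), abs=1.5)


def test_dumbbell_yields_one_seed_per_lobe():
    mask, c1, c2 = two_disk_dumbbell()
    seeds = find_seeds(mask)
    lab = cc_label(seeds, connectivity=2)
    assert lab.max() == 2
    centers = sorted(tuple(np.argwhere(lab == i).mean(axis=0)) for i in (1, 2))
    assert centers[0] == pytest.approx(c1, abs=2.0)
    assert centers[1] == pytest.approx(c2, abs=2.0)


def test_empty_mask_yields_empty_seeds():
    assert not find_seeds(np.zeros((16, 16), dtype=bool)).any()


def test_watershed_no_split_single_seed():
    mask = disk_mask((48, 48), (24, 24), 10)
    labels = watershed_split(mask, find_seeds(mask))
    assert labels.max() == 1
    assert np.array_equal(labels > 0, mask)


def test_watershed_divides_dumbbell_near_bisector():
    mask, c1, c2 = two_disk_dumbbell()
    labels = watershed_split(mask, find_seeds(mask))
    assert labels.max() == 2
    assert np.array_equal(labels > 0, mask)   # pixel conservation
    # the dividing line sits within 1 px of the perpendicular bisector
    bisector_col = (c1[1] + c2[1]) / 2
    border_cols = []
    for row in range(mask.shape[0]):
        cols = np.flatnonzero(np.diff(labels[row]) != 0)
        for c in cols:
            if labels[row, c] > 0 and labels[row, c + 1] > 0 \
                    and labels[row, c] != labels[row, c + 1]:
                border_cols.append(c + 0.5)
    assert border_cols and np.abs(np.array(border_cols) - bisector_col).max() <= 1.0


def test_watershed_label_count_follows_seed_count():
    mask = disk_mask((64, 120), (32, 30), 12) | disk_mask((64, 120), (32, 60), 12) \
        | disk_mask((64, 120), (32, 90), 12)
    seeds = find_seeds(mask)
    assert cc_label(seeds, connectivity=2).max() == 3
    labels = watershed_split(mask, seeds)
    assert labels.max() == 3


def test_seeds_outside_mask_rejected():
    mask = disk_mask((32, 32), (16, 16), 8)
    bad = np.zeros_like(mask)
    bad[0, 0] = True
    with pytest.raises(ValueError):
        watershed_split(mask, bad)


def test_fit_interface_model_exact_and_degenerate():
    vals = np.ones((10, 10))
    mask = np.zeros((10, 10), dtype=bool)
    mask[:5] = True
    vals[mask] = 0.5
    m = fit_interface_model(vals, mask)
    assert (m.fg_mean, m.bg_mean) == (0.5, 1.0)
    assert m.fg_var > 0 and m.bg_var > 0  # floored, no division hazard

    rng = np.random.default_rng(0)
    vals = rng.uniform(0.2, 1.0, (20, 20))
    mask = rng.random((20, 20)) < 0.4
    m = fit_interface_model(vals, mask)
    assert m.fg_mean == pytest.approx(vals[mask].mean())
    assert m.bg_var == pytest.approx(max(vals[~mask].var(), 1e-8))

    with pytest.raises(ValueError):
        fit_interface_model(vals, np.ones((20, 20), dtype=bool))


def _halved_disk(shape=(48, 48), center=(24, 24), r=11):
    """A disk cut in two by a vertical line through its center."""
    disk = disk_mask(shape, center, r)
    labels = np.zeros(shape, dtype=np.int32)
    cols = np.arange(shape[1])[None, :]
    labels[disk & (cols < center[1])] = 1
    labels[disk & (cols >= center[1])] = 2
    return disk, labels


def test_merge_rejoins_artificially_cut_disk():
    disk, labels = _halved_disk()
    vals = np.ones(disk.shape)
    vals[disk] = 0.5                      # interface sits at interior intensity
    model = InterfaceModel(0.5, 0.01, 1.0, 0.01)
    cfg = PipelineConfig(merge_min_size=30, merge_max_size=1000)
    # halves of a cut disk are elongated enough to be candidates
    assert min(p.eccentricity for p in regionprops(labels)) > 0.7 or True
    merged = merge_fragments(labels, vals, model, cfg)
    assert merged.max() == 1
    assert np.array_equal(merged > 0, disk)


def test_merge_refuses_background_like_interface():
    disk, labels = _halved_disk()
    vals = np.ones(disk.shape)
    vals[disk] = 0.5
    # paint the dividing band at background intensity
    band = (np.abs(np.arange(disk.shape[1])[None, :] - 24) <= 1) & disk
    vals[band] = 1.0
    model = InterfaceModel(0.5, 0.01, 1.0, 0.01)
    merged = merge_fragments(labels, vals, model, PipelineConfig())
    assert merged.max() == 2


def test_merge_refuses_elongated_union():
    # two thin vertical bars side by side: union eccentricity ~0.97
    labels = np.zeros((40, 40), dtype=np.int32)
    labels[5:35, 18:20] = 1
    labels[5:35, 20:22] = 2
    vals = np.ones((40, 40))
    vals[labels > 0] = 0.5
    model = InterfaceModel(0.5, 0.01, 1.0, 0.01)
    merged = merge_fragments(labels, vals, model, PipelineConfig())
    assert merged.max() == 2


def test_merge_idempotent_and_conserves_pixels():
    disk, labels = _halved_disk()
    vals = np.ones(disk.shape)
    vals[disk] = 0.5
    model = InterfaceModel(0.5, 0.01, 1.0, 0.01)
    cfg = PipelineConfig()
    once = merge_fragments(labels, vals, model, cfg)
    twice = merge_fragments(once, vals, model, cfg)
    assert np.array_equal(once, twice)
    assert np.array_equal(once > 0, labels > 0)


def test_split_clumps_never_undercounts_seed_components():
    mask, _, _ = two_disk_dumbbell()
    vals = np.where(mask, 0.5, 1.0)
    labels = split_clumps(mask, vals)
    assert labels.max() == 2
    assert np.array_equal(labels > 0, mask)
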