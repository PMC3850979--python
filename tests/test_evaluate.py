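"""Matching categories, detection metrics, and density conversion."""

import numpy as np
import pytest

from brightcell.evaluate import (EvaluationCounts, compute_metrics, density,
                                 match_objects, metrics_from_tallies)
from brightcell.synthetic import SceneSpec, generate_frame

from conftest import disk_mask


def test_perfect_segmentation_counts_all_correct():
    _, truth = generate_frame(SceneSpec(image_shape=(256, 256), n_cells=10,
                                        debris_count=0, seed=9))
    counts = match_objects(truth.labels, truth.labels)
    assert counts.n_cells_truth == truth.n_cells
    assert counts.correct == truth.n_cells
    assert (counts.missed, counts.over_segmented, counts.under_segmented,
            counts.debris) == (0, 0, 0, 0)
    counts = compute_metrics(counts)
    assert (counts.accuracy, counts.specificity, counts.sensitivity) == (1, 1, 1)


def test_merged_pair_counts_one_tp_one_fn():
    truth = np.zeros((64, 96), dtype=np.int32)
    truth[disk_mask((64, 96), (32, 30), 10)] = 1
    truth[disk_mask((64, 96), (32, 55), 10)] = 2
    detected = (truth > 0).astype(np.int32)  # one blob over both cells
    counts = match_objects(detected, truth)
    assert counts.under_segmented == 2
    assert counts.n_under_objects == 1
    assert (counts.tp, counts.fn, counts.fp) == (1, 1, 0)


def test_fragmented_cell_counts_largest_as_tp_rest_fp():
    truth = np.zeros((64, 64), dtype=np.int32)
    truth[disk_mask((64, 64), (32, 32), 14)] = 1
    detected = np.zeros_like(truth)
    cols = np.arange(64)[None, :]
    detected[(truth == 1) & (cols < 28)] = 1
    detected[(truth == 1) & (cols >= 28) & (cols < 36)] = 2
    detected[(truth == 1) & (cols >= 36)] = 3
    counts = match_objects(detected, truth)
    assert counts.over_segmented == 1
    assert counts.surplus_fragments == 2
    assert (counts.tp, counts.fp, counts.fn) == (1, 2, 0)


def test_debris_and_missed():
    truth = np.zeros((64, 64), dtype=np.int32)
    truth[disk_mask((64, 64), (20, 20), 8)] = 1
    detected = np.zeros_like(truth)
    detected[disk_mask((64, 64), (48, 48), 5)] = 1   # overlaps nothing
    counts = match_objects(detected, truth)
    assert counts.missed == 1
    assert counts.debris == 1
    assert (counts.tp, counts.fp, counts.fn) == (0, 1, 1)


@pytest.mark.parametrize("tp,fp,fn,acc2", [
    (84, 13, 6, 0.82),       # moderate-density timepoint
    (5632, 96, 205, 0.95),   # high-density timepoint
    (7136, 329, 278, 0.92),  # densest timepoint
])
def test_accuracy_formula_reproduces_published_rounding(tp, fp, fn, acc2):
    counts = metrics_from_tallies(tp, fp, fn)
    assert round(counts.accuracy, 2) == acc2


def test_specificity_sensitivity_formulas():
    counts = metrics_from_tallies(36, 6, 1)
    assert round(counts.specificity, 2) == 0.86
    assert round(counts.sensitivity, 2) == 0.97


def test_zero_denominator_yields_nan_with_warning():
    with pytest.warns(UserWarning):
        counts = compute_metrics(EvaluationCounts())
    assert np.isnan(counts.accuracy)


def test_accuracy_never_exceeds_other_metrics():
    rng = np.random.default_rng(0)
    for _ in range(200):
        tp, fp, fn = rng.integers(1, 1000), rng.integers(0, 300), rng.integers(0, 300)
        c = metrics_from_tallies(int(tp), int(fp), int(fn))
        assert c.accuracy <= min(c.specificity, c.sensitivity) + 1e-12


def test_evaluation_report_pools_and_averages():
    from brightcell.evaluate import evaluation_report
    a = EvaluationCounts(n_cells_truth=10, correct=9, missed=1,
                         tp=9, fp=0, fn=1)
    b = EvaluationCounts(n_cells_truth=20, correct=16, missed=2,
                         over_segmented=2, surplus_fragments=2,
                         tp=18, fp=2, fn=2)
    df = evaluation_report([a, b], ["f0", "f1"])
    assert list(df["frame"]) == ["f0", "f1", "pooled"]
    pooled = df.iloc[-1]
    assert pooled["tp"] == 27 and pooled["fp"] == 2 and pooled["fn"] == 3
    assert pooled["accuracy"] == pytest.approx(27 / 32)
    # per-frame rows carry their own rates (mean/sd view left to the caller)
    assert df.iloc[0]["accuracy"] == pytest.approx(0.9)


def test_density_conversion():
    # 1000x1000 px at 1 um/px is exactly 1 mm^2
    mean, sd, dens = density([100], 1.0, (1000, 1000))
    assert (mean, sd) == (100.0, 0.0)
    mean, sd, dens = density([0, 0], 1.0, (1000, 1000))
    assert mean == 0.0
    with pytest.raises(ValueError):
        density([1], 0.0, (100, 100))


def test_density_recovers_generator_truth():
    spec = SceneSpec(image_shape=(512, 512), n_cells=30, seed=10)
    _, truth = generate_frame(spec)
    mean, _, _ = density([truth.n_cells], 2.0, spec.image_shape)
    area_mm2 = 512 * 512 * 4 * 1e-6
    assert mean == pytest.approx(truth.n_cells / area_mm2)
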