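"""Segmentation scoring against ground truth.

Each true cell falls in exactly one category: correctly segmented, missed,
over-segmented (split into several detected fragments), or under-segmented
(sharing one detected object with other true cells). Detection-level tallies
follow the counting convention for cell detection: true positives are
complete cell bodies, the largest fragment of each over-segmented cell, and
one cell per under-segmented object; false positives are debris and surplus
cell fragments; false negatives are missed cells and the remaining cells of
under-segmented objects. The derived rates are

    accuracy    = TP / (TP + FP + FN)
    specificity = TP / (TP + FP)
    sensitivity = TP / (TP + FN)

Manual evaluation in the source protocol assigned categories by eye; the
automated matcher here uses centroid containment with a pixel-overlap
fallback, with thresholds that are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class EvaluationCounts:
    """Category tallies and detection metrics for one or more frames.

    ``under_segmented`` counts every true cell that shares a detected object
    with another true cell; ``n_under_objects`` counts the merged detected
    objects themselves (one TP each). ``surplus_fragments`` are detected
    fragments of over-segmented cells beyond the largest one.
    """

    n_cells_truth: int = 0
    correct: int = 0
    missed: int = 0
    over_segmented: int = 0
    under_segmented: int = 0
    debris: int = 0
    n_under_objects: int = 0
    surplus_fragments: int = 0
    tp: int = 0
    fp: int = 0
    fn: int = 0
    accuracy: float = float("nan")
    specificity: float = float("nan")
    sensitivity: float = float("nan")

    def __add__(self, other: "EvaluationCounts") -> "EvaluationCounts":
        pooled = EvaluationCounts(
            *(getattr(self, f) + getattr(other, f)
              for f in ("n_cells_truth", "correct", "missed", "over_segmented",
                        "under_segmented", "debris", "n_under_objects",
                        "surplus_fragments", "tp", "fp", "fn")))
        return pooled


def match_objects(detected: np.ndarray, truth: np.ndarray,
                  min_overlap: float = 0.5) -> EvaluationCounts:
    """Match detected objects to true cells and tally the categories.

    Each true cell is assigned the detected object containing its centroid
    (falling back to maximal pixel overlap when the centroid pixel is empty).
    A cell is correct when it is the sole cell assigned to its object, no
    surplus fragments cover it, and the object overlaps at least
    ``min_overlap`` of the cell's area. Detected objects claimed by no cell
    are debris; detected objects mostly inside a cell but not its primary
    object are surplus fragments (marking the cell over-segmented).
    """
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    if detected.shape != truth.shape:
        raise ValueError("detected and truth grids must share a shape")
    nt, nd = int(truth.max()), int(detected.max())
    # joint histogram of (truth, detected) labels
    joint = np.bincount(truth.ravel().astype(np.int64) * (nd + 1) + detected.ravel(),
                        minlength=(nt + 1) * (nd + 1)).reshape(nt + 1, nd + 1)
    truth_area = joint.sum(axis=1)
    det_area = joint.sum(axis=0)

    # primary detected object per true cell
    primary = np.zeros(nt + 1, dtype=np.int64)
    if nt and truth_area[1:].min() == 0:
        raise ValueError("truth labels must be contiguous from 1")
    if nt:
        centroids = ndimage.center_of_mass(np.ones_like(truth), truth,
                                           np.arange(1, nt + 1))
        for t, (crow, ccol) in enumerate(centroids, start=1):
            d = int(detected[int(round(crow)), int(round(ccol))]) if nd else 0
            if d == 0 or joint[t, d] == 0:
                overlaps = joint[t, 1:]
                d = int(np.argmax(overlaps)) + 1 if nd and overlaps.max() > 0 else 0
            primary[t] = d

    # fragments: detected objects that are not anyone's primary object but
    # sit mostly inside one true cell
    claimed = set(primary[primary > 0].tolist())
    fragments_of = np.zeros(nd + 1, dtype=np.int64)
    for d in range(1, nd + 1):
        if d in claimed:
            continue
        t_best = int(np.argmax(joint[1:, d])) + 1 if joint[1:, d].max() > 0 else 0
        if t_best and joint[t_best, d] / det_area[d] > 0.5:
            fragments_of[d] = t_best

    counts = EvaluationCounts(n_cells_truth=nt)
    cells_per_object = np.bincount(primary[1:][primary[1:] > 0], minlength=nd + 1)
    for t in range(1, nt + 1):
        d = primary[t]
        if d == 0:
            counts.missed += 1
        elif cells_per_object[d] >= 2:
            counts.under_segmented += 1
        elif np.any(fragments_of == t):
            counts.over_segmented += 1
            counts.surplus_fragments += int(np.sum(fragments_of == t))
        elif joint[t, d] / truth_area[t] >= min_overlap:
            counts.correct += 1
        else:
            counts.missed += 1  # primary object barely covers the cell
    counts.n_under_objects = int(np.sum(cells_per_object >= 2))
    counts.debris = int(sum(1 for d in range(1, nd + 1)
                            if d not in claimed and fragments_of[d] == 0))
    counts.tp = counts.correct + counts.over_segmented + counts.n_under_objects
    counts.fp = counts.debris + counts.surplus_fragments
    counts.fn = counts.missed + (counts.under_segmented - counts.n_under_objects)
    return counts


def compute_metrics(counts: EvaluationCounts) -> EvaluationCounts:
    """Fill accuracy / specificity / sensitivity from tp, fp, fn."""
    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)")
            return float("nan")
        return num / den

    counts.accuracy = ratio(counts.tp, counts.tp + counts.fp + counts.fn, "accuracy")
    counts.specificity = ratio(counts.tp, counts.tp + counts.fp, "specificity")
    counts.sensitivity = ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    return counts


def metrics_from_tallies(tp: int, fp: int, fn: int) -> EvaluationCounts:
    """Metrics straight from detection tallies (e.g. a published table)."""
    return compute_metrics(EvaluationCounts(tp=tp, fp=fp, fn=fn))


def evaluation_report(per_frame: "list[EvaluationCounts]",
                      frame_ids: "list[str] | None" = None):
    """Per-frame metric table plus a pooled summary row.

    Pooled metrics recompute the rates from summed tallies; the per-frame
    rows expose the mean ± sd view (frames are weighted equally there, so
    sparse early frames influence the average as strongly as dense ones).
    """
    import pandas as pd

    rows = []
    ids = frame_ids or [f"frame{i}" for i in range(len(per_frame))]
    for fid, c in zip(ids, per_frame):
        c = compute_metrics(c)
        rows.append({"frame": fid, "n_cells_truth": c.n_cells_truth,
                     "correct": c.correct, "missed": c.missed,
                     "over_segmented": c.over_segmented,
                     "under_segmented": c.under_segmented, "debris": c.debris,
                     "tp": c.tp, "fp": c.fp, "fn": c.fn,
                     "accuracy": c.accuracy, "specificity": c.specificity,
                     "sensitivity": c.sensitivity})
    pooled = EvaluationCounts()
    for c in per_frame:
        pooled = pooled + c
    pooled = compute_metrics(pooled)
    rows.append({"frame": "pooled", "n_cells_truth": pooled.n_cells_truth,
                 "correct": pooled.correct, "missed": pooled.missed,
                 "over_segmented": pooled.over_segmented,
                 "under_segmented": pooled.under_segmented,
                 "debris": pooled.debris, "tp": pooled.tp, "fp": pooled.fp,
                 "fn": pooled.fn, "accuracy": pooled.accuracy,
                 "specificity": pooled.specificity,
                 "sensitivity": pooled.sensitivity})
    return pd.DataFrame(rows)


def density(counts_per_frame: "list[int] | np.ndarray", pixel_size_um: float,
            image_shape: tuple[int, int]) -> tuple[float, float, np.ndarray]:
    """Cell densities per mm²: per-frame values plus their mean ± sd.

    The frame area is height·width·pixel_size_um² in µm², i.e. that value
    times 10⁻⁶ in mm².
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    counts = np.asarray(counts_per_frame, dtype=float)
    area_mm2 = image_shape[0] * image_shape[1] * pixel_size_um ** 2 * 1e-6
    dens = counts / area_mm2
    return float(dens.mean()), float(dens.std(ddof=1)) if len(dens) > 1 else 0.0, dens
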