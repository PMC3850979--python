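"""Per-object measurement and the final filtering that defines "cells".

Two features suffice to clean the detections: area in pixels removes debris
and dead-cell fragments (< 50 px by default), and the eccentricity of the
equal-second-moment ellipse removes line-like artifacts (> 0.99). Objects
touching an image border are removed as well because their features are
truncated.
"""

from __future__ import annotations

import numpy as np
from skimage.measure import regionprops

from .io import CellObject


def measure_objects(labels: np.ndarray) -> list[CellObject]:
    """Measure area, eccentricity, centroid, and border contact per label."""
    labels = np.asarray(labels)
    h, w = labels.shape
    border = set(np.unique(np.concatenate([
        labels[0], labels[-1], labels[:, 0], labels[:, -1]])).tolist())
    out = []
    for p in regionprops(labels):
        out.append(CellObject(
            label=int(p.label),
            area_px=int(p.area),
            eccentricity=float(p.eccentricity),
            centroid=(float(p.centroid[0]), float(p.centroid[1])),
            touches_border=p.label in border,
        ))
    return out


def filter_objects(objects: list[CellObject], labels: np.ndarray,
                   min_area: int = 50, max_eccentricity: float = 0.99,
                   remove_border: bool = True,
                   ) -> tuple[np.ndarray, list[CellObject]]:
    """Discard non-cell objects; relabel survivors contiguously from 1.

    An object is discarded when its area is below ``min_area`` OR its
    eccentricity exceeds ``max_eccentricity`` (boundary-inclusive as stated:
    area == min_area and eccentricity == max_eccentricity are kept), or when
    it touches an image border and ``remove_border`` is set.
    """
    labels = np.asarray(labels)
    kept = [o for o in objects
            if o.area_px >= min_area
            and o.eccentricity <= max_eccentricity
            and not (remove_border and o.touches_border)]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    relabeled = []
    for new_id, obj in enumerate(sorted(kept, key=lambda o: o.label), start=1):
        lut[obj.label] = new_id
        relabeled.append(CellObject(new_id, obj.area_px, obj.eccentricity,
                                    obj.centroid, obj.touches_border))
    return lut[labels], relabeled
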