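"""Maximally stable extremal regions for dark cell bodies.

Out-of-focus bright-field cells appear as evenly dark blobs on a bright
background, so segmentation reduces to finding threshold-set components that
are stable across gray levels. For a threshold τ the (4-connected) components
of {I ≤ τ} form a nested component tree as τ sweeps 0…255. A component R at
level τ is scored by its relative area change over a symmetric interval Δ:

    variation(R, τ) = (|R⁺| − |R⁻|) / |R|

where R⁺ is the component at level min(τ+Δ, 255) that contains R and R⁻ is
the largest component at level max(τ−Δ, 0) contained in R (area 0 if none).
A component is reported when its variation is a local minimum along its
branch of the component tree — no child at τ−1 scores lower, and the parent
at τ+1 scores no lower (ties go to the coarser region) — and it passes the
size and variation filters. The component spanning the whole frame (the tree
root) is never a region: it has no boundary and is not extremal.

The semantics here are deliberately exact and enumerable: the accepted
regions are identical, pixel for pixel, to a brute-force sweep that builds
every threshold component explicitly and applies the same formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label

from .io import CorrectedImage, ForegroundMask, RawImage

# complementary connectivities avoid topological paradoxes: 4-connected
# foreground components, 8-connected background/holes
FG_CONNECTIVITY = 1
BG_CONNECTIVITY = 2


@dataclass
class ExtremalRegion:
    """One accepted maximally stable extremal region."""

    rows: np.ndarray
    cols: np.ndarray
    level: int          # threshold τ at which the region is maximally stable
    variation: float

    @property
    def area(self) -> int:
        return len(self.rows)

    def pixel_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(zip(self.rows.tolist(), self.cols.tolist()))


def to_8bit(corrected: CorrectedImage | np.ndarray,
            min_span: float = 0.3) -> np.ndarray:
    """Linearly rescale a ratio image's [min, 1.0] range onto [0, 255].

    The corrected image lives in (0, 1] with background pinned at 1.0; the
    threshold sweep needs discrete gray levels, so the occupied range is
    stretched to the full 8-bit scale. The lower anchor is never raised
    above ``1 - min_span``: cell bodies darken the ratio image by far more
    than ``min_span``, so a frame whose darkest pixel is within that span of
    the background holds no foreground, and stretching its sensor noise to
    full scale would fabricate extremal structure. A constant image maps to
    all-255. Applying the map twice (with re-derived minimum) is idempotent.
    """
    vals = corrected.pixels if isinstance(corrected, CorrectedImage) else np.asarray(corrected)
    lo = min(float(vals.min()), 1.0 - min_span)
    scaled = (vals - lo) / (1.0 - lo) * 255.0
    return np.rint(np.clip(scaled, 0, 255)).astype(np.uint8)


def detect_mser(image8: np.ndarray | RawImage, delta: int = 5,
                min_size: int = 30, max_size: int = 4000,
                max_variation: float = 1.0,
                polarity: str = "dark") -> list[ExtremalRegion]:
    """Detect maximally stable dark (or bright) extremal regions.

    Parameters mirror the classical MSER parameterisation: ``delta`` is the
    stability interval Δ, ``min_size``/``max_size`` bound the region area in
    pixels, and ``max_variation`` caps the relative area change. With
    ``polarity="bright"`` the image is inverted first, so inverting the
    input and swapping polarity returns identical regions.
    """
    img = image8.pixels if isinstance(image8, RawImage) else np.asarray(image8)
    if img.dtype != np.uint8:
        raise ValueError("detect_mser requires an 8-bit image")
    if delta < 1 or min_size < 1 or max_size < min_size:
        raise ValueError("invalid MSER parameters")
    if polarity == "bright":
        img = (255 - img.astype(np.int16)).astype(np.uint8)
    elif polarity != "dark":
        raise ValueError("polarity must be 'dark' or 'bright'")

    h, w = img.shape
    npx = h * w
    flat_index = np.arange(npx)

    # --- pass 1: per-level component summaries (labels themselves are transient)
    areas: list[np.ndarray] = []       # areas[τ][c] for c = 1..ncomp
    reps: list[np.ndarray] = []        # min flat pixel index per component
    parents: list[np.ndarray] = []     # parents[τ][c] = containing label at τ+1
    ncomps = np.zeros(256, dtype=int)
    prev_reps = None
    for tau in range(256):
        lab = cc_label(img <= tau, connectivity=FG_CONNECTIVITY)
        n = int(lab.max())
        ncomps[tau] = n
        flat = lab.ravel()
        areas.append(np.bincount(flat, minlength=n + 1))
        if n:
            rep = ndimage.minimum(flat_index, labels=flat,
                                  index=np.arange(1, n + 1)).astype(np.int64)
        else:
            rep = np.empty(0, dtype=np.int64)
        reps.append(np.concatenate(([0], rep)))  # index 0 unused
        if prev_reps is not None:
            parents.append(flat[prev_reps[1:]] if len(prev_reps) > 1
                           else np.empty(0, dtype=flat.dtype))
        prev_reps = reps[-1]
    parents.append(np.empty(0, dtype=np.int64))  # τ=255 has no parent level

    def ancestor(tau_from: int, tau_to: int, comp_ids: np.ndarray) -> np.ndarray:
        """Map component labels at tau_from to containing labels at tau_to."""
        out = comp_ids
        for t in range(tau_from, tau_to):
            out = np.concatenate(([0], parents[t]))[out]
        return out

    # --- pass 2: variation per (component, level)
    variations: list[np.ndarray] = []
    for tau in range(256):
        n = ncomps[tau]
        v = np.full(n + 1, np.inf)
        if n:
            hi, lo = min(tau + delta, 255), max(tau - delta, 0)
            ids = np.arange(1, n + 1)
            a_plus = areas[hi][ancestor(tau, hi, ids)]
            a_minus = np.zeros(n + 1, dtype=np.int64)
            if ncomps[lo]:
                lo_ids = np.arange(1, ncomps[lo] + 1)
                anc = ancestor(lo, tau, lo_ids)
                np.maximum.at(a_minus, anc, areas[lo][lo_ids])
            v[1:] = (a_plus - a_minus[1:]) / areas[tau][1:]
        variations.append(v)

    # --- pass 3: local-minimum test along the component tree, plus filters
    accepted: dict[tuple[int, int], tuple[int, int]] = {}  # canonical key → (τ, label)
    for tau in range(256):
        n = ncomps[tau]
        if not n:
            continue
        v = variations[tau][1:]
        area = areas[tau][1:]
        # minimum child variation at τ−1, grouped by containing component
        child_min = np.full(n + 1, np.inf)
        if tau > 0 and ncomps[tau - 1]:
            np.minimum.at(child_min, parents[tau - 1],
                          variations[tau - 1][1:])
        ok = v <= child_min[1:]
        if tau < 255:
            ok &= v < variations[tau + 1][parents[tau]]
        ok &= (area >= min_size) & (area <= max_size) & (area < npx)
        ok &= v <= max_variation
        for c in np.flatnonzero(ok) + 1:
            key = (int(area[c - 1]), int(reps[tau][c]))
            if key not in accepted:  # same pixel set stable over several τ
                accepted[key] = (tau, int(c))

    # --- extraction: re-threshold each accepted level once, group its pixels
    by_level: dict[int, list[int]] = {}
    for tau, c in accepted.values():
        by_level.setdefault(tau, []).append(c)
    regions = []
    for tau in sorted(by_level):
        lab = cc_label(img <= tau, connectivity=FG_CONNECTIVITY)
        flat = lab.ravel()
        wanted = np.zeros(ncomps[tau] + 1, dtype=bool)
        wanted[by_level[tau]] = True
        sel = np.flatnonzero(wanted[flat])
        order = sel[np.argsort(flat[sel], kind="stable")]
        bounds = np.searchsorted(flat[order], np.array(sorted(by_level[tau])))
        bounds = np.append(bounds, len(order))
        for i, c in enumerate(sorted(by_level[tau])):
            pix = order[bounds[i]:bounds[i + 1]]
            regions.append(ExtremalRegion(pix // w, pix % w, tau,
                                          float(variations[tau][c])))
    return regions


def regions_to_mask(regions: list[ExtremalRegion],
                    shape: tuple[int, int]) -> ForegroundMask:
    """Union all regions (merging nested ones) and fill interior holes.

    Nested accepted regions simply union into their outermost member. Any
    background component (8-connected) with no path to an image border is an
    interior hole and is flipped to foreground.
    """
    mask = np.zeros(shape, dtype=bool)
    for region in regions:
        mask[region.rows, region.cols] = True
    return ForegroundMask(fill_holes(mask))


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background components that do not touch an image border."""
    bg = cc_label(~mask, connectivity=BG_CONNECTIVITY)
    border = np.unique(np.concatenate([
        bg[0], bg[-1], bg[:, 0], bg[:, -1]]))
    hole = ~np.isin(bg, border) & (bg > 0)
    return mask | hole
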