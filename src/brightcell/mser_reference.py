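"""Exhaustive reference implementation of the extremal-region detector.

This module re-derives maximally stable extremal regions the slow, obvious
way: it materializes every connected component of every threshold set
{I ≤ τ}, τ = 0…255, as an explicit pixel set, computes each component's
variation from set containment, and applies the local-minimum and filter
rules by direct enumeration. It shares no code or data structures with
:mod:`brightcell.mser` — components come from a different labeling routine
and all containment tests are set operations — so agreement between the two
is a meaningful check of the fast detector. Only use it on small images.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_STRUCT4 = ndimage.generate_binary_structure(2, 1)


def mser_reference(img: np.ndarray, delta: int = 5, min_size: int = 30,
                   max_size: int = 4000, max_variation: float = 1.0,
                   ) -> set[frozenset[tuple[int, int]]]:
    """All accepted dark extremal regions of an 8-bit image, as pixel sets."""
    img = np.asarray(img)
    if img.dtype != np.uint8:
        raise ValueError("8-bit input required")
    h, w = img.shape
    npx = h * w

    comps: list[list[frozenset]] = []
    for tau in range(256):
        lab, n = ndimage.label(img <= tau, structure=_STRUCT4)
        level = []
        for c in range(1, n + 1):
            rr, cc = np.nonzero(lab == c)
            level.append(frozenset(zip(rr.tolist(), cc.tolist())))
        comps.append(level)

    def containing(level: int, pixel: tuple[int, int]) -> frozenset:
        for comp in comps[level]:
            if pixel in comp:
                return comp
        raise AssertionError("threshold sets must nest")

    variation: list[dict[frozenset, float]] = []
    for tau in range(256):
        hi, lo = min(tau + delta, 255), max(tau - delta, 0)
        level_v = {}
        for comp in comps[tau]:
            rep = next(iter(comp))
            a_plus = len(containing(hi, rep))
            # components at the lower level nest inside comp iff their
            # representative pixel is a member
            a_minus = max((len(d) for d in comps[lo] if next(iter(d)) in comp),
                          default=0)
            level_v[comp] = (a_plus - a_minus) / len(comp)
        variation.append(level_v)

    accepted: set[frozenset] = set()
    for tau in range(256):
        for comp in comps[tau]:
            v = variation[tau][comp]
            if tau > 0:
                children = [d for d in comps[tau - 1] if next(iter(d)) in comp]
                if any(variation[tau - 1][d] < v for d in children):
                    continue
            if tau < 255:
                parent = containing(tau + 1, next(iter(comp)))
                if not v < variation[tau + 1][parent]:
                    continue
            if not (min_size <= len(comp) <= max_size and len(comp) < npx):
                continue
            if v > max_variation:
                continue
            accepted.add(comp)
    return accepted
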