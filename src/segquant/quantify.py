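"""Touching-cell quantification by iterative morphological erosion.

Touching cells form a single connected component in the segmented mask.
Eroding the mask repeatedly with the radius-1 diamond element breaks the
thin necks between touching cells before the cell bodies disappear; each
connected component is harvested as a cell *seed* the moment its area
drops below the area threshold ``S_0``, then removed from the mask, and
the loop continues until the mask is empty.  Seeds collected over all
iterations are pairwise disjoint, and their centroids are the reported
cell centres.

``S_0`` separates "still a clump" from "a single cell": the default
estimate is the mean connected-component area after a few erosions of
the mask (eroded cells approximate single-cell cores even when the raw
components are clumps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, ParameterError
from .filters import DIAMOND

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SeedSet:
    """Labelled cell seeds accumulated over the erosion iterations.

    ``labels`` holds one positive integer per seed region (0 elsewhere);
    ``iteration_of`` maps each label to the erosion iteration at which
    the seed was extracted (1 = extracted from the unfiltered mask).
    """

    labels: np.ndarray
    iteration_of: dict[int, int] = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.iteration_of)


@dataclass(frozen=True)
class QuantificationResult:
    """Per-cell centroids plus the seed regions they came from.

    Centroids are 0-based (row, col) means of the seed pixels.
    """

    centroids: list[tuple[float, float]]
    seeds: SeedSet
    iterations: int


def estimate_area_threshold(blobs: np.ndarray, pre_erosions: int = 6) -> float:
    """Estimate ``S_0`` as the mean blob area after ``pre_erosions`` erosions.

    Falls back to the mean area of the uneroded blobs when the erosions
    empty the mask entirely.
    """
    if pre_erosions < 0:
        raise ParameterError("pre_erosions must be >= 0")
    mask = np.asarray(blobs, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("cannot estimate an area threshold from an empty mask")
    eroded = mask
    if pre_erosions:
        eroded = ndimage.binary_erosion(mask, structure=DIAMOND, iterations=pre_erosions)
    if not eroded.any():
        eroded = mask
    labels, n = ndimage.label(eroded, structure=_EIGHT)
    areas = ndimage.sum_labels(eroded, labels, index=np.arange(1, n + 1))
    return float(np.mean(areas))


def iterative_erosion_quantify(blobs: np.ndarray, area_threshold: float) -> SeedSet:
    """Erode the mask iteratively, harvesting sub-``S_0`` components as seeds.

    Each iteration first extracts every connected component whose area is
    already below ``area_threshold`` (whole, un-eroded — it is a single
    cell) and then erodes the remainder once with the diamond element.
    The loop terminates because erosion strictly shrinks a nonempty mask.
    """
    if area_threshold <= 0:
        raise ParameterError("area_threshold must be > 0")
    mask = np.asarray(blobs, dtype=bool).copy()
    seeds = np.zeros(mask.shape, dtype=np.int32)
    iteration_of: dict[int, int] = {}
    next_label = 1
    iteration = 0
    while mask.any():
        iteration += 1
        labels, n = ndimage.label(mask, structure=_EIGHT)
        areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        for lab in np.flatnonzero(areas < area_threshold) + 1:
            region = labels == lab
            seeds[region] = next_label
            iteration_of[next_label] = iteration
            next_label += 1
            mask[region] = False
        if mask.any():
            mask = ndimage.binary_erosion(mask, structure=DIAMOND)
    return SeedSet(labels=seeds, iteration_of=iteration_of)


def centroids(seeds: SeedSet) -> QuantificationResult:
    """Arithmetic-mean (row, col) centre of each seed region."""
    labs = sorted(seeds.iteration_of)
    if labs:
        cents = ndimage.center_of_mass(seeds.labels > 0, seeds.labels, labs)
        cents = [(float(r), float(c)) for r, c in cents]
    else:
        cents = []
    n_iter = max(seeds.iteration_of.values(), default=0)
    return QuantificationResult(centroids=cents, seeds=seeds, iterations=n_iter)


def quantify(blobs: np.ndarray, area_threshold: float | None = None,
             pre_erosions: int = 6) -> QuantificationResult:
    """Full quantification: estimate ``S_0`` if not given, seed, locate centres."""
    mask = np.asarray(blobs, dtype=bool)
    if not mask.any():
        return QuantificationResult(centroids=[], seeds=SeedSet(
            labels=np.zeros(mask.shape, dtype=np.int32)), iterations=0)
    s0 = estimate_area_threshold(mask, pre_erosions) if area_threshold is None \
        else float(area_threshold)
    return centroids(iterative_erosion_quantify(mask, s0))
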