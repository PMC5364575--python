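"""Synthetic fixtures: three-class test images and cell-field images.

Two image families exercise the whole framework without any external
data:

* **three-class images** — a flat background (gray 50) carrying a darker
  object (gray 120) and a brighter object (gray 220), optionally
  degraded by additive Gaussian noise and by an iterative moving-average
  blur.  Their histograms are the canonical testbed for the slope
  difference distribution: three isolated spikes that smooth into three
  real SDD peaks separated by real valleys.

* **cell fields** — bright elliptical cells on a darker background, with
  the defects the optional filters exist to fix: pairs of touching
  cells (for the iterative-erosion separator), threadlike noise blobs of
  thickness <= 2 px, some attached to cells (for the noise blob filter),
  periodic boundary roughness and small interior holes (for the boundary
  smoothing filter).  Ground truth comes back as a label mask, per-cell
  centroids, the binary cell-region mask and a 1-px-dilated edge band.

All randomness flows through a single integer seed; a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.segmentation import find_boundaries

from .errors import ParameterError
from .filters import DIAMOND


@dataclass(frozen=True)
class GroundTruth:
    """Reference segmentation of a synthetic image."""

    labels: np.ndarray
    centroids: dict[int, tuple[float, float]]

    @property
    def region_mask(self) -> np.ndarray:
        """Binary mask of all cell regions."""
        return self.labels > 0

    @property
    def edge_band(self) -> np.ndarray:
        """Cell contours dilated by 1 px (for gradient-mask calibration)."""
        edges = find_boundaries(self.labels, mode="thick")
        return ndimage.binary_dilation(edges, structure=DIAMOND)

    @property
    def n_cells(self) -> int:
        return len(self.centroids)


def truth_from_labels(labels: np.ndarray) -> GroundTruth:
    """Build a :class:`GroundTruth` (with centroids) from a label mask."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    cents = {}
    if ids.size:
        for lab, (r, c) in zip(
            ids, ndimage.center_of_mass(labels > 0, labels, ids)
        ):
            cents[int(lab)] = (float(r), float(c))
    return GroundTruth(labels=labels, centroids=cents)


# --------------------------------------------------------------------------
# three-class images


@dataclass(frozen=True)
class ThreeClassSpec:
    """Geometry of the flat three-class test image.

    Rectangles are (row0, row1, col0, col1) with exclusive upper bounds;
    gray levels must be strictly increasing within [0, 255] and the
    background must keep the pixel-count majority.
    """

    shape: tuple[int, int] = (200, 200)
    levels: tuple[int, int, int] = (50, 120, 220)
    dark_object: tuple[int, int, int, int] = (30, 100, 20, 150)
    bright_object: tuple[int, int, int, int] = (110, 190, 30, 165)

    def __post_init__(self) -> None:
        lo, mid, hi = self.levels
        if not (0 <= lo < mid < hi <= 255):
            raise ParameterError("levels must be strictly increasing in [0, 255]")


def make_three_class(spec: ThreeClassSpec | None = None) -> tuple[np.ndarray, GroundTruth]:
    """Noise-free three-class image plus its object label mask."""
    spec = spec or ThreeClassSpec()
    img = np.full(spec.shape, spec.levels[0], dtype=np.int64)
    labels = np.zeros(spec.shape, dtype=np.int32)
    for lab, (rect, level) in enumerate(
        [(spec.dark_object, spec.levels[1]), (spec.bright_object, spec.levels[2])], 1
    ):
        r0, r1, c0, c1 = rect
        img[r0:r1, c0:c1] = level
        labels[r0:r1, c0:c1] = lab
    return img, truth_from_labels(labels)


def add_gaussian_noise(image: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Additive Gaussian noise, clipped to [0, 255] and rounded."""
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    image = np.asarray(image, dtype=float)
    if sigma == 0:
        return np.floor(image + 0.5).astype(np.int64)
    rng = np.random.default_rng(seed)
    noisy = image + rng.normal(0.0, sigma, size=image.shape)
    return np.floor(np.clip(noisy, 0, 255) + 0.5).astype(np.int64)


def iterative_blur(image: np.ndarray, window: int = 5, passes: int = 10) -> np.ndarray:
    """Iterated normalized box-filter blur with replicate borders."""
    if window < 1 or window % 2 == 0:
        raise ParameterError("window must be a positive odd integer")
    if passes < 0:
        raise ParameterError("passes must be >= 0")
    out = np.asarray(image, dtype=float)
    for _ in range(passes):
        out = ndimage.uniform_filter(out, size=window, mode="nearest")
    return np.floor(np.clip(out, 0, 255) + 0.5).astype(np.int64)


def make_gaussian_mixture(
    means: tuple[float, float] = (90.0, 160.0),
    sigma: float = 15.0,
    weight: float = 0.5,
    shape: tuple[int, int] = (200, 200),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-region image whose histogram is a two-Gaussian mixture.

    A fraction ``weight`` of the columns holds the first class at mean
    ``means[0]``, the rest the second class at ``means[1]``; both carry
    i.i.d. Gaussian noise of the same ``sigma``.  Returns the clipped
    8-bit image and the boolean mask of the second (brighter) class.
    """
    if not 0 < weight < 1:
        raise ParameterError("weight must be in (0, 1)")
    rng = np.random.default_rng(seed)
    split = int(round(weight * shape[1]))
    img = np.empty(shape, dtype=float)
    img[:, :split] = means[0]
    img[:, split:] = means[1]
    img += rng.normal(0.0, sigma, size=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[:, split:] = True
    return np.floor(np.clip(img, 0, 255) + 0.5).astype(np.int64), mask


# --------------------------------------------------------------------------
# cell fields


@dataclass(frozen=True)
class CellFieldSpec:
    """Parameters of a synthetic cell-field image.

    ``n_cells`` counts all cells; ``touching_pairs`` of them are placed
    as pairs whose boundaries overlap by ``pair_overlap`` pixels, so the
    binary mask has ``n_cells - touching_pairs`` connected components.
    Threadlike noise blobs are random polylines of thickness
    ``noise_thickness``; a fraction of them is attached to a cell
    boundary.  Boundary roughness is a periodic radial perturbation of
    relative amplitude ``roughness_amplitude``; ``n_holes`` small holes
    are punched into cell interiors in the rendered image only (the
    ground truth keeps the full cell).
    """

    shape: tuple[int, int] = (256, 256)
    n_cells: int = 20
    touching_pairs: int = 4
    axis_range: tuple[float, float] = (9.0, 14.0)
    cell_level: int = 200
    bg_level: int = 60
    noise_sigma: float = 6.0
    n_noise_blobs: int = 8
    noise_thickness: int = 2
    noise_attached_fraction: float = 0.5
    noise_length: int = 60
    roughness_amplitude: float = 0.06
    roughness_frequency: int = 7
    n_holes: int = 6
    hole_radius: int = 2
    pair_overlap: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2 * self.touching_pairs:
            raise ParameterError("n_cells must cover all touching pairs")
        if not 0 <= self.bg_level < self.cell_level <= 255:
            raise ParameterError("need 0 <= bg_level < cell_level <= 255")


@dataclass
class _Cell:
    center: tuple[float, float]
    axes: tuple[float, float]
    theta: float
    rough_amp: float
    rough_freq: int
    rough_phase: float

    def radius_along(self, direction: float) -> float:
        a, b = self.axes
        d = direction - self.theta
        return 1.0 / np.sqrt((np.cos(d) / a) ** 2 + (np.sin(d) / b) ** 2)

    def render(self, labels: np.ndarray, lab: int) -> None:
        a, b = self.axes
        r0, c0 = self.center
        rad = max(a, b) * (1 + self.rough_amp) + 2
        rr = np.arange(max(0, int(r0 - rad)), min(labels.shape[0], int(r0 + rad) + 1))
        cc = np.arange(max(0, int(c0 - rad)), min(labels.shape[1], int(c0 + rad) + 1))
        gr, gc = np.meshgrid(rr - r0, cc - c0, indexing="ij")
        ct, st = np.cos(self.theta), np.sin(self.theta)
        u = gr * ct + gc * st
        v = -gr * st + gc * ct
        rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        ang = np.arctan2(v, u)
        boundary = 1.0 + self.rough_amp * np.sin(self.rough_freq * ang + self.rough_phase)
        inside = rho <= boundary
        block = labels[rr[0]: rr[-1] + 1, cc[0]: cc[-1] + 1]
        block[inside & (block == 0)] = lab


def _place_cells(spec: CellFieldSpec, rng: np.random.Generator) -> list[_Cell]:
    def new_cell(center, theta=None) -> _Cell:
        ax = sorted(rng.uniform(*spec.axis_range, size=2), reverse=True)
        return _Cell(
            center=center,
            axes=(ax[0], ax[1]),
            theta=rng.uniform(0, np.pi) if theta is None else theta,
            rough_amp=spec.roughness_amplitude,
            rough_freq=spec.roughness_frequency,
            rough_phase=rng.uniform(0, 2 * np.pi),
        )

    h, w = spec.shape
    margin = spec.axis_range[1] * (1 + spec.roughness_amplitude) + 4
    cells: list[_Cell] = []

    def clear_of_others(cands: list[_Cell], gap: float = 6.0) -> bool:
        for cand in cands:
            for other in cells:
                d = np.hypot(
                    cand.center[0] - other.center[0], cand.center[1] - other.center[1]
                )
                if d < max(cand.axes) + max(other.axes) + gap:
                    return False
        return True

    attempts = 0
    while len(cells) < 2 * spec.touching_pairs and attempts < 10_000:
        attempts += 1
        # pair members touch tip-to-tip: long axes along the join direction,
        # boundaries overlapping by pair_overlap px, so the union has a
        # genuine neck at the contact point
        direction = rng.uniform(0, 2 * np.pi)
        c1 = new_cell(
            (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)),
            theta=direction,
        )
        c2 = new_cell((0.0, 0.0), theta=direction)
        d = c1.radius_along(direction) + c2.radius_along(direction + np.pi) \
            - spec.pair_overlap
        center2 = (
            c1.center[0] + d * np.cos(direction),
            c1.center[1] + d * np.sin(direction),
        )
        if not (margin <= center2[0] <= h - margin and margin <= center2[1] <= w - margin):
            continue
        c2.center = center2
        if clear_of_others([c1, c2]):
            cells.extend([c1, c2])
    while len(cells) < spec.n_cells and attempts < 20_000:
        attempts += 1
        c = new_cell((rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)))
        if clear_of_others([c]):
            cells.append(c)
    if len(cells) < spec.n_cells:
        raise ParameterError(
            f"could not place {spec.n_cells} cells of this size in shape {spec.shape}"
        )
    return cells


def _draw_polyline(mask: np.ndarray, start, rng, length: int, thickness: int) -> None:
    """Add one threadlike blob: a gently curving polyline of the given thickness.

    The curvature is kept small so the thread never folds onto itself;
    a folded thread would locally exceed the nominal thickness and stop
    being "tenuous".  The candidate is verified to vanish under a
    radius-``thickness`` opening and redrawn otherwise.
    """
    h, w = mask.shape
    for _ in range(8):
        r, c = float(start[0]), float(start[1])
        heading = rng.uniform(0, 2 * np.pi)
        pts = []
        for _ in range(length):
            pts.append((int(round(r)), int(round(c))))
            heading += rng.normal(0, 0.12)
            r = np.clip(r + np.sin(heading), 1, h - 2)
            c = np.clip(c + np.cos(heading), 1, w - 2)
        line = np.zeros_like(mask)
        rr, cc = zip(*pts)
        line[rr, cc] = True
        if thickness > 1:
            line = ndimage.binary_dilation(
                line, structure=DIAMOND, iterations=thickness - 1
            )
        gone = not ndimage.binary_erosion(
            line, structure=DIAMOND, iterations=thickness + 1
        ).any()
        if gone:
            mask |= line
            return
    mask |= line


def make_cell_field(spec: CellFieldSpec | None = None) -> tuple[np.ndarray, GroundTruth]:
    """Render a cell field and its ground truth.

    Returns the noisy 8-bit-range image and a :class:`GroundTruth`
    whose labels cover exactly the rendered cell regions (threadlike
    noise and interior holes are image defects, not truth).
    """
    spec = spec or CellFieldSpec()
    rng = np.random.default_rng(spec.seed)
    labels = np.zeros(spec.shape, dtype=np.int32)
    cells = _place_cells(spec, rng)
    for lab, cell in enumerate(cells, 1):
        cell.render(labels, lab)
    truth = truth_from_labels(labels)

    img = np.full(spec.shape, float(spec.bg_level))
    img[labels > 0] = spec.cell_level

    # threadlike noise blobs, some attached to cell boundaries
    noise = np.zeros(spec.shape, dtype=bool)
    edge_pts = np.argwhere(find_boundaries(labels, mode="outer"))
    for k in range(spec.n_noise_blobs):
        if edge_pts.size and rng.uniform() < spec.noise_attached_fraction:
            start = edge_pts[rng.integers(len(edge_pts))]
        else:
            start = (rng.uniform(2, spec.shape[0] - 3), rng.uniform(2, spec.shape[1] - 3))
        _draw_polyline(noise, start, rng, spec.noise_length, spec.noise_thickness)
    img[noise] = spec.cell_level

    # interior holes (image defect only)
    hole_hosts = rng.choice(len(cells), size=min(spec.n_holes, len(cells)), replace=False)
    yy, xx = np.mgrid[-spec.hole_radius: spec.hole_radius + 1,
                      -spec.hole_radius: spec.hole_radius + 1]
    disk = yy**2 + xx**2 <= spec.hole_radius**2
    for idx in hole_hosts:
        cell = cells[idx]
        off = rng.uniform(-0.35, 0.35, size=2) * min(cell.axes)
        hr = int(round(cell.center[0] + off[0]))
        hc = int(round(cell.center[1] + off[1]))
        r0, c0 = hr - spec.hole_radius, hc - spec.hole_radius
        sl = (slice(max(0, r0), min(spec.shape[0], r0 + disk.shape[0])),
              slice(max(0, c0), min(spec.shape[1], c0 + disk.shape[1])))
        dsl = disk[: sl[0].stop - sl[0].start, : sl[1].stop - sl[1].start]
        img[sl][dsl] = spec.bg_level

    noisy = add_gaussian_noise(img, spec.noise_sigma, int(rng.integers(2**31)))
    return noisy, truth
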