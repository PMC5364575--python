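"""Mask clean-up filters: noise-blob removal and boundary smoothing.

Two optional stages sit between the union segmentation and the
iterative-erosion quantification:

* the **noise blob filter** — ``N_l`` erosions followed by ``N_l``
  dilations with the 4-connected radius-1 diamond element (a
  morphological opening).  Threadlike blobs of half-width below ``N_l``
  disappear in the erosions and are never restored, while massive cell
  blobs survive nearly unchanged;

* the **boundary smoothing filter** — every blob contour (outer contours
  and interior holes) is traced, contours shorter than the shape-noise
  threshold ``T_sn`` are discarded (deleting tiny blobs and filling small
  holes), the surviving contours' x- and y-coordinate sequences are
  low-pass filtered with a periodic DFT of bandwidth ``W_b``, and the
  blobs are refilled from the smoothed contours.  Boundary roughness and
  small holes would otherwise fragment cells into several seeds during
  iterative erosion.

Contour convention: Moore-neighbour tracing on the 8-connected contour,
outer contours clockwise and holes counterclockwise, 0-based (row, col)
coordinates at pixel centres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .errors import ParameterError

#: The 4-connected radius-1 disk (5-point diamond) used by every
#: morphological step in the framework.
DIAMOND = ndimage.generate_binary_structure(2, 1)

_EIGHT = np.ones((3, 3), dtype=bool)

# Moore neighbourhood in clockwise order (row grows downward):
# W, NW, N, NE, E, SE, S, SW
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def noise_blob_filter(mask: np.ndarray, repeats: int = 3) -> np.ndarray:
    """Open the mask with the diamond element, ``repeats`` times each way.

    Erodes ``repeats`` times then dilates ``repeats`` times with the same
    element; the result is contained in the input and the operation is
    idempotent.
    """
    if repeats < 1:
        raise ParameterError(f"repeats must be >= 1, got {repeats}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    return ndimage.binary_opening(mask, structure=DIAMOND, iterations=int(repeats))


@dataclass(frozen=True)
class BoundaryTrace:
    """A closed contour of one blob or one hole.

    ``points`` is an ordered (N, 2) array of 0-based (row, col) pixel
    coordinates; the first point is adjacent to the last.  ``kind`` is
    ``"outer"`` or ``"hole"``; ``parent`` is the blob id the contour
    belongs to.
    """

    points: np.ndarray
    kind: str = "outer"
    parent: int = 0

    def __len__(self) -> int:
        return len(self.points)


def _moore_trace(mask: np.ndarray, start: tuple[int, int]) -> list[tuple[int, int]]:
    """Clockwise Moore-neighbour contour of the component containing ``start``.

    ``start`` must be the component's row-major first pixel so that its
    west neighbour is background.  Terminates on re-entering the start
    pixel from the initial direction (Jacob's criterion).
    """
    h, w = mask.shape

    def fg(p):
        return 0 <= p[0] < h and 0 <= p[1] < w and mask[p]

    contour = [start]
    # backtrack: the background pixel we came from; start scanning after it
    backtrack = (start[0], start[1] - 1)
    current = start
    first_move: tuple[tuple[int, int], tuple[int, int]] | None = None
    while True:
        # index of backtrack in the Moore ring around current
        off = (backtrack[0] - current[0], backtrack[1] - current[1])
        k0 = _MOORE.index(off)
        nxt = None
        for step in range(1, 9):
            k = (k0 + step) % 8
            cand = (current[0] + _MOORE[k][0], current[1] + _MOORE[k][1])
            if fg(cand):
                nxt = cand
                break
            backtrack = cand
        if nxt is None:  # isolated pixel
            break
        move = (current, nxt)
        if first_move is None:
            first_move = move
        elif move == first_move:
            contour.pop()  # the revisited start was appended last round
            break
        current = nxt
        contour.append(current)
        if len(contour) > 4 * mask.size:  # safety net, cannot trigger on valid input
            raise RuntimeError("contour tracing failed to terminate")
    return contour


def trace_boundaries(mask: np.ndarray) -> list[BoundaryTrace]:
    """Trace all outer contours and hole contours of a binary mask.

    One outer trace per 8-connected foreground component; one hole trace
    per 4-connected background component fully enclosed by foreground.
    Hole traces are reported counterclockwise and carry the enclosing
    blob's id as ``parent``.
    """
    mask = np.asarray(mask, dtype=bool)
    traces: list[BoundaryTrace] = []
    if not mask.any():
        return traces
    labels, n = ndimage.label(mask, structure=_EIGHT)
    slices = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        sub = labels[sl] == lab
        rr, cc = np.nonzero(sub)
        k = np.lexsort((cc, rr))[0]  # row-major first pixel
        pts = _moore_trace(sub, (int(rr[k]), int(cc[k])))
        pts_arr = np.asarray(pts, dtype=np.int64)
        pts_arr += (sl[0].start, sl[1].start)
        traces.append(BoundaryTrace(points=pts_arr, kind="outer", parent=lab))

    holes, nh = ndimage.label(~mask, structure=DIAMOND)
    if nh:
        border = np.unique(
            np.concatenate([holes[0], holes[-1], holes[:, 0], holes[:, -1]])
        )
        open_bg = set(border.tolist())
        hole_slices = ndimage.find_objects(holes)
        for lab in range(1, nh + 1):
            if lab in open_bg:
                continue
            sl = hole_slices[lab - 1]
            sub = holes[sl] == lab
            rr, cc = np.nonzero(sub)
            k = np.lexsort((cc, rr))[0]
            pts = _moore_trace(sub, (int(rr[k]), int(cc[k])))
            pts_arr = np.asarray(pts, dtype=np.int64)
            pts_arr += (sl[0].start, sl[1].start)
            # parent blob: the label just above the hole's first pixel
            pr, pc = int(rr[k]) + sl[0].start - 1, int(cc[k]) + sl[1].start
            parent = int(labels[pr, pc]) if pr >= 0 else 0
            traces.append(
                BoundaryTrace(points=pts_arr[::-1].copy(), kind="hole", parent=parent)
            )
    return traces


def boundary_length_filter(
    traces: list[BoundaryTrace], threshold: float
) -> list[BoundaryTrace]:
    """Keep contours longer than the shape-noise threshold ``T_sn``.

    A removed hole contour means the hole is filled; a removed outer
    contour deletes the blob together with its holes.
    """
    if threshold < 0:
        raise ParameterError("threshold must be >= 0")
    kept_outer = {t.parent for t in traces if t.kind == "outer" and len(t) > threshold}
    out = []
    for t in traces:
        if len(t) <= threshold:
            continue
        if t.kind == "hole" and t.parent not in kept_outer:
            continue
        out.append(t)
    return out


def default_shape_noise_threshold(
    traces: list[BoundaryTrace], fraction: float = 0.25
) -> float:
    """``T_sn`` as a fraction of the mean outer-contour length."""
    lengths = [len(t) for t in traces if t.kind == "outer"]
    if not lengths:
        return 0.0
    return fraction * float(np.mean(lengths))


def smooth_boundary(trace: BoundaryTrace, bandwidth: int) -> BoundaryTrace:
    """Low-pass filter a contour's coordinate sequences with a periodic DFT.

    The row and column sequences (period ``N_j``) each keep Fourier
    coefficients ``k in [0, W_b] + [N_j - W_b, N_j - 1]``; the filtered
    real-valued contour is rounded back to the pixel grid.  The k = 0
    coefficient is untouched, so the contour centroid is conserved up to
    rounding.
    """
    w = int(bandwidth)
    n = len(trace)
    if w < 1:
        raise ParameterError("bandwidth must be >= 1")
    if n < 2 * w + 2:
        raise ParameterError(
            f"contour of {n} points too short for bandwidth {w} (need >= {2 * w + 2})"
        )
    pts = trace.points.astype(float)
    keep = np.zeros(n, dtype=bool)
    keep[: w + 1] = True
    keep[n - w:] = True
    out = np.empty_like(pts)
    for d in range(2):
        spec = np.fft.fft(pts[:, d])
        spec[~keep] = 0.0
        out[:, d] = np.fft.ifft(spec).real
    rounded = np.floor(out + 0.5).astype(np.int64)
    return BoundaryTrace(points=rounded, kind=trace.kind, parent=trace.parent)


def rebuild_blobs(traces: list[BoundaryTrace], shape: tuple[int, int]) -> np.ndarray:
    """Refill a binary mask from (possibly smoothed) contours.

    Each outer contour is scan-filled (even-odd rule) together with its
    own pixels; each hole contour is filled the same way and subtracted.
    """
    out = np.zeros(shape, dtype=bool)
    for t in traces:
        if t.kind == "outer":
            out |= _fill_contour(t.points, shape)
    for t in traces:
        if t.kind == "hole":
            out &= ~_fill_contour(t.points, shape)
    return out


def _fill_contour(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    filled = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(points[:, 0], points[:, 1], shape=shape)
    filled[rr, cc] = True
    r = np.clip(points[:, 0], 0, shape[0] - 1)
    c = np.clip(points[:, 1], 0, shape[1] - 1)
    inb = (points[:, 0] >= 0) & (points[:, 0] < shape[0]) & \
          (points[:, 1] >= 0) & (points[:, 1] < shape[1])
    filled[r[inb], c[inb]] = True
    return filled


def smooth_mask(
    mask: np.ndarray,
    shape_noise_threshold: float | None = None,
    bandwidth: int = 10,
) -> np.ndarray:
    """Apply the full boundary smoothing filter to a mask.

    Traces contours, drops those not longer than ``T_sn`` (default: a
    quarter of the mean outer-contour length), smooths the survivors and
    refills.  Contours too short for the requested bandwidth are kept
    unsmoothed with a per-contour reduced bandwidth when possible.
    """
    traces = trace_boundaries(mask)
    if not traces:
        return np.zeros_like(np.asarray(mask, dtype=bool))
    t_sn = (
        default_shape_noise_threshold(traces)
        if shape_noise_threshold is None
        else shape_noise_threshold
    )
    kept = boundary_length_filter(traces, t_sn)
    smoothed = []
    for t in kept:
        w_eff = min(int(bandwidth), (len(t) - 2) // 2)
        smoothed.append(smooth_boundary(t, w_eff) if w_eff >= 1 else t)
    return rebuild_blobs(smoothed, np.asarray(mask).shape)
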