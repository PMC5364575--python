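"""Calibration of the threshold-selection parameters (N, W).

The line-fit length ``N`` and the DFT bandwidth ``W`` depend on the image
type.  Two calibration routes are provided:

* **F-measure grid search** — when ground-truth masks exist, every pair
  ``(N, W)`` with ``N in [3, 60]`` and ``W in [2, 50]`` is scored by the
  F-measure between the automatic binarization and the truth, and the
  best pair wins.  The F-measure here is defined through the overlap
  ratios ``P = |S_SD & S_m| / |S_m|`` and ``R = |S_SD & S_m| / |S_SD|``
  and equals the Dice coefficient ``2|A & B| / (|A| + |B|)`` exactly.

* **Rational calibration** — benchmark-free: starting from the defaults
  ``N = 15, W = 10``, increase ``N`` until the slope difference
  distribution shows exactly as many dominant peaks as the image has
  pixel classes (a larger ``N`` suppresses small peaks and merges
  adjacent ones).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import sdd as _sdd
from .errors import CalibrationError, DegenerateInputError, ParameterError, SegquantError

N_RANGE = (3, 60)
W_RANGE = (2, 50)


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated ``(N, W)`` pair plus, in grid mode, the full score grid."""

    fit_points: int
    bandwidth: int
    mode: str
    score_grid: np.ndarray | None = None  # indexed [N - 3, W - 2]


def f_measure(auto_mask: np.ndarray, manual_mask: np.ndarray) -> float:
    """F-measure between an automatic and a manual segmentation mask."""
    a = np.asarray(auto_mask, dtype=bool)
    m = np.asarray(manual_mask, dtype=bool)
    if a.shape != m.shape:
        raise ParameterError(f"mask shapes differ: {a.shape} vs {m.shape}")
    n_m = int(m.sum())
    if n_m == 0:
        raise DegenerateInputError("manual mask is empty; F-measure undefined")
    inter = int((a & m).sum())
    if inter == 0:
        return 0.0
    p = inter / n_m
    r = inter / int(a.sum())
    return 2.0 * p * r / (p + r)


def _truth_suffix_counts(image: np.ndarray, truth: np.ndarray):
    """Per-threshold pixel counts for fast F-measure evaluation.

    Returns ``(ge_all, ge_in)`` where ``ge_all[t]`` is the number of
    pixels with value >= t and ``ge_in[t]`` the number of those inside
    the truth mask.
    """
    vals = image.ravel()
    counts_all = np.bincount(vals, minlength=256)
    counts_in = np.bincount(vals[truth.ravel()], minlength=256)
    ge_all = np.cumsum(counts_all[::-1])[::-1]
    ge_in = np.cumsum(counts_in[::-1])[::-1]
    return ge_all, ge_in


def _f_at_threshold(ge_all, ge_in, n_truth: int, t: int, polarity: str) -> float:
    if polarity == "bright":
        n_auto = int(ge_all[t])
        inter = int(ge_in[t])
    else:
        n_auto = int(ge_all[0] - ge_all[t])
        inter = int(ge_in[0] - ge_in[t])
    if inter == 0 or n_auto == 0:
        return 0.0
    return 2.0 * inter / (n_truth + n_auto)


def calibrate_grid(
    images: list[np.ndarray],
    truths: list[np.ndarray],
    template: _sdd.ThresholdRequest | None = None,
    polarity: str = "bright",
) -> CalibrationResult:
    """Exhaustive (N, W) search maximising the mean F-measure.

    ``template`` fixes the class count and separation case; its
    ``fit_points``/``bandwidth`` are overridden by the scan.  Pairs for
    which threshold selection fails score 0.  Ties resolve to the
    smallest ``W``, then the smallest ``N``.
    """
    if not images or len(images) != len(truths):
        raise ParameterError("need >= 1 image and as many truth masks")
    if template is None:
        template = _sdd.ThresholdRequest()

    prepared = []
    for img, truth in zip(images, truths):
        truth = np.asarray(truth, dtype=bool)
        if not truth.any():
            raise DegenerateInputError("a truth mask is empty")
        rescaled = _sdd.ensure_8bit(img)
        raw = _sdd.normalized_histogram(rescaled)
        ge_all, ge_in = _truth_suffix_counts(rescaled, truth)
        prepared.append((raw, ge_all, ge_in, int(truth.sum())))

    n_lo, n_hi = N_RANGE
    w_lo, w_hi = W_RANGE
    grid = np.zeros((n_hi - n_lo + 1, w_hi - w_lo + 1))
    best = (-1.0, 0, 0)
    for w in range(w_lo, w_hi + 1):
        smoothed = [_sdd.dft_lowpass(raw, w) for raw, *_ in prepared]
        for n in range(n_lo, n_hi + 1):
            req = _sdd.ThresholdRequest(
                class_count=template.class_count,
                case_id=template.case_id,
                fit_points=n,
                bandwidth=w,
            )
            scores = []
            for (raw, ge_all, ge_in, n_truth), sm in zip(prepared, smoothed):
                try:
                    dist = _sdd.slope_difference(sm, n)
                    peaks = _sdd.select_real_peaks(dist, req.class_count)
                    res = _sdd.select_threshold(dist, peaks, req, sm, raw)
                    scores.append(
                        _f_at_threshold(ge_all, ge_in, n_truth, res.threshold, polarity)
                    )
                except SegquantError:
                    scores.append(0.0)
            mean_f = float(np.mean(scores))
            grid[n - n_lo, w - w_lo] = mean_f
            if mean_f > best[0]:
                best = (mean_f, n, w)
    return CalibrationResult(
        fit_points=best[1], bandwidth=best[2], mode="f_measure", score_grid=grid
    )


def calibrate_rational(
    image: np.ndarray,
    class_count: int,
    bandwidth: int = 10,
    start: int = 15,
    rel_magnitude: float = 0.1,
) -> CalibrationResult:
    """Benchmark-free calibration of ``N`` by dominant-peak counting.

    Starting from ``N = start`` (default 15) with the given bandwidth
    (default 10), increases ``N`` until the SDD shows exactly
    ``class_count`` dominant peaks.  Fails when no ``N`` up to 60 does.

    A peak counts as dominant at 10% of the largest magnitude: on the
    continuous histograms of practical images the smoothing harmonics are
    far below that, while a minority pixel class can still reach it.
    (Histograms made of isolated spikes ring more strongly; the stricter
    default of :meth:`SlopeDifferenceDistribution.dominant_peaks` applies
    there.)
    """
    if class_count < 2:
        raise ParameterError("class_count must be >= 2")
    rescaled = _sdd.ensure_8bit(image)
    raw = _sdd.normalized_histogram(rescaled)
    smoothed = _sdd.dft_lowpass(raw, bandwidth)
    for n in range(start, N_RANGE[1] + 1):
        dist = _sdd.slope_difference(smoothed, n)
        if len(dist.dominant_peaks(rel_magnitude)) == class_count:
            return CalibrationResult(fit_points=n, bandwidth=bandwidth, mode="rational")
    raise CalibrationError(
        f"no N in [{start}, {N_RANGE[1]}] yields exactly {class_count} dominant peaks"
    )
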