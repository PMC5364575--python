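"""Threshold selection from the slope difference distribution (SDD).

The image histogram is modelled as a mixture of unimodal (typically
Gaussian) class distributions.  The SDD is the difference between the
least-squares line slope fitted to the ``N`` histogram points to the right
of a bin and the slope fitted to the ``N`` points to its left:

    s(i) = a2(i) - a1(i),   i = N+1 ... 255-N

Its local maxima mark the cluster centres of the pixel classes and its
local minima (valleys) mark the gray levels that separate adjacent
classes, so a threshold is read off as the position of the deepest valley
between two class centres.  Before the SDD is computed the histogram is
normalised by its largest bin and smoothed by a low-pass DFT filter of
bandwidth ``W``; the smoothing removes high-frequency counting noise while
preserving the histogram shape, at the cost of introducing small-amplitude
harmonic ripples ("pseudo" peaks and valleys) over flat histogram
stretches.  Pseudo extrema are rejected by magnitude: real extrema are
much larger.

Two user-facing parameters control the procedure and are what the
calibration module tunes: the line-fit length ``N`` (default 15) and the
filter bandwidth ``W`` (default 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CalibrationError,
    DegenerateInputError,
    ParameterError,
    ThresholdSelectionError,
)

N_BINS = 256

#: Relative magnitude below which an SDD extremum is considered a pseudo
#: peak/valley produced by the DFT smoothing harmonics.  The strongest
#: ringing sidelobes of an isolated histogram spike reach roughly a fifth
#: of the principal magnitude, so the cut sits just above them.
PSEUDO_REL_MAGNITUDE = 0.25


def rescale_to_255(image: np.ndarray) -> np.ndarray:
    """Rescale a non-negative image linearly so its maximum maps to 255.

    Values are rounded half-up to integers, giving an 8-bit-range image
    suitable for a 256-bin histogram.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise DegenerateInputError("empty image")
    if image.min() < 0:
        raise ParameterError("image must be non-negative")
    mx = image.max()
    if mx <= 0:
        raise DegenerateInputError("all-zero image cannot be rescaled")
    return np.floor(255.0 * image / mx + 0.5).astype(np.int64)


def normalized_histogram(image: np.ndarray) -> np.ndarray:
    """256-bin histogram normalised by the count of its fullest bin.

    The returned vector ``P`` satisfies ``max(P) == 1`` exactly.
    """
    image = np.asarray(image)
    vals = image.ravel().astype(np.int64)
    if vals.min() < 0 or vals.max() > 255:
        raise ParameterError("image values must lie in [0, 255]")
    counts = np.bincount(vals, minlength=N_BINS).astype(float)
    return counts / counts.max()


def dft_lowpass(signal: np.ndarray, bandwidth: int) -> np.ndarray:
    """Low-pass filter a length-256 signal in the DFT domain.

    Keeps coefficients ``k = 0..W`` and their conjugate partners
    ``k = 256-W..255`` and zeroes the rest; the output is the pointwise
    magnitude of the inverse transform.  ``W = 128`` keeps the full band
    and is the identity for non-negative input.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape != (N_BINS,):
        raise ParameterError(f"expected a length-{N_BINS} signal")
    w = int(bandwidth)
    if not 1 <= w <= N_BINS // 2:
        raise ParameterError(f"bandwidth must be in [1, {N_BINS // 2}], got {w}")
    spec = np.fft.fft(signal)
    keep = np.zeros(N_BINS, dtype=bool)
    keep[: w + 1] = True
    keep[N_BINS - w:] = True
    spec[~keep] = 0.0
    return np.abs(np.fft.ifft(spec))


@dataclass(frozen=True)
class SlopeDifferenceDistribution:
    """The discrete SDD signal together with its detected extrema.

    ``s[k]`` is the slope difference at gray level ``positions[k]``;
    ``peaks`` / ``valleys`` are ``(position, magnitude)`` pairs for every
    local maximum / minimum, pseudo ones included.
    """

    s: np.ndarray
    positions: np.ndarray
    fit_points: int
    peaks: list[tuple[int, float]] = field(default_factory=list)
    valleys: list[tuple[int, float]] = field(default_factory=list)

    def dominant_peaks(self, rel: float = PSEUDO_REL_MAGNITUDE) -> list[tuple[int, float]]:
        """Peaks whose magnitude is at least ``rel`` of the largest peak."""
        return _dominant(self.peaks, rel)

    def dominant_valleys(self, rel: float = PSEUDO_REL_MAGNITUDE) -> list[tuple[int, float]]:
        """Valleys whose magnitude is at least ``rel`` of the deepest valley."""
        return _dominant(self.valleys, rel)


def _dominant(extrema: list[tuple[int, float]], rel: float) -> list[tuple[int, float]]:
    if not extrema:
        return []
    ref = max(abs(m) for _, m in extrema)
    return [(p, m) for p, m in extrema if abs(m) >= rel * ref]


def _window_slopes(signal: np.ndarray, n: int) -> np.ndarray:
    """Least-squares line slopes of every length-``n`` window of ``signal``.

    Entry ``j`` is the slope fitted to ``signal[j : j + n]`` against
    unit-spaced abscissae (closed form for equally spaced x).
    """
    c = np.arange(n, dtype=float) - (n - 1) / 2.0
    c /= n * (n * n - 1) / 12.0
    return np.correlate(signal, c, mode="valid")


def slope_difference(smoothed: np.ndarray, fit_points: int) -> SlopeDifferenceDistribution:
    """Compute the SDD of a smoothed 256-bin histogram.

    At each interior bin ``i`` the slope ``a1`` is fitted to the ``N``
    bins left of ``i`` and ``a2`` to the ``N`` bins right of it, both
    windows parameterized outward from ``i`` so that ``s(i)`` equals the
    left slope minus the right slope on ascending gray levels, for ``i``
    in ``[N+1, 255-N]``.  Under this sign convention a class centre
    (rising then falling histogram) is an SDD maximum and a separating
    gray level an SDD minimum.  Local extrema are located where the
    discrete derivative of ``s`` changes sign; on flat plateaus the
    leftmost index is reported.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    if smoothed.shape != (N_BINS,):
        raise ParameterError(f"expected a length-{N_BINS} smoothed histogram")
    n = int(fit_points)
    if not 3 <= n <= 60:
        raise ParameterError(f"fit_points must be in [3, 60], got {n}")

    slopes = _window_slopes(smoothed, n)  # slopes[j] fits bins j..j+n-1
    positions = np.arange(n + 1, N_BINS - n)
    # left window of i starts at i-n, right window starts at i+1
    a1 = slopes[positions - n]
    a2 = slopes[positions + 1]
    s = a1 - a2

    # deadband relative to the histogram's amplitude: slope differences of
    # pure floating-point residue must not register as extrema
    peaks, valleys = _local_extrema(s, tol=1e-12 * (np.abs(smoothed).max() + 1e-300))
    return SlopeDifferenceDistribution(
        s=s,
        positions=positions,
        fit_points=n,
        peaks=[(int(positions[k]), float(s[k])) for k in peaks],
        valleys=[(int(positions[k]), float(s[k])) for k in valleys],
    )


def _local_extrema(s: np.ndarray, tol: float = 0.0) -> tuple[list[int], list[int]]:
    """Indices of local maxima and minima of ``s`` (leftmost on plateaus).

    Steps with magnitude at most ``tol`` count as flat.
    """
    d = np.diff(s)
    if tol > 0:
        d = np.where(np.abs(d) <= tol, 0.0, d)
    d = np.sign(d)
    peaks: list[int] = []
    valleys: list[int] = []
    prev_sign = 0
    prev_k = -1
    for k in np.flatnonzero(d):
        sk = d[k]
        if prev_sign > 0 and sk < 0:
            peaks.append(prev_k + 1)
        elif prev_sign < 0 and sk > 0:
            valleys.append(prev_k + 1)
        prev_sign = sk
        prev_k = int(k)
    return peaks, valleys


@dataclass(frozen=True)
class ThresholdRequest:
    """Parameters of one threshold selection.

    ``class_count`` is the number of pixel classes in the image
    (background included); ``case_id`` picks which class boundary to
    extract: case 1 separates the background from all object classes, and
    case ``m >= 2`` separates object class ``m-1`` from object class ``m``
    along increasing intensity.
    """

    class_count: int = 2
    case_id: int = 1
    fit_points: int = 15
    bandwidth: int = 10

    def __post_init__(self) -> None:
        if self.class_count < 2:
            raise ParameterError("class_count must be >= 2")
        if not 1 <= self.case_id <= self.class_count - 1:
            raise ParameterError(
                f"case_id must be in [1, {self.class_count - 1}], got {self.case_id}"
            )
        if not 3 <= self.fit_points <= 60:
            raise ParameterError("fit_points must be in [3, 60]")
        if not 2 <= self.bandwidth <= 128:
            raise ParameterError("bandwidth must be in [2, 128]")


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a threshold selection, with full diagnostics."""

    threshold: int
    real_peaks: list[int]
    chosen_valley: tuple[int, float]
    sdd: SlopeDifferenceDistribution
    smoothed_histogram: np.ndarray
    raw_histogram: np.ndarray


def select_real_peaks(sdd: SlopeDifferenceDistribution, class_count: int) -> list[int]:
    """The ``class_count`` largest-magnitude SDD peaks, sorted by position.

    Raises :class:`CalibrationError` when fewer peaks were detected: a
    too-large ``N`` has merged or suppressed class peaks and the
    parameters need recalibration.
    """
    if class_count < 1:
        raise ParameterError("class_count must be >= 1")
    if len(sdd.peaks) < class_count:
        raise CalibrationError(
            f"only {len(sdd.peaks)} SDD peaks detected, need {class_count}; "
            f"recalibrate fit_points/bandwidth"
        )
    by_mag = sorted(sdd.peaks, key=lambda pm: abs(pm[1]), reverse=True)
    chosen = sorted(p for p, _ in by_mag[:class_count])
    return [int(p) for p in chosen]


def _case_interval(
    real_peaks: list[int], background_peak: int, case_id: int
) -> tuple[int, int]:
    """Gray-level interval (lo, hi) whose valley is the requested threshold."""
    peaks = sorted(real_peaks)
    b = peaks.index(background_peak)
    if case_id == 1:
        if b == 0:
            return peaks[0], peaks[1]
        if b == len(peaks) - 1:
            return peaks[-2], peaks[-1]
        # interior background: separate it from the side holding more classes
        left, right = b, len(peaks) - 1 - b
        if left == right:
            raise ThresholdSelectionError(
                "background peak is interior with equally many object classes "
                "on both sides; case 1 is ambiguous"
            )
        if left > right:
            return peaks[b - 1], peaks[b]
        return peaks[b], peaks[b + 1]
    objects = [p for k, p in enumerate(peaks) if k != b]
    if case_id - 1 >= len(objects):
        raise ParameterError(f"case_id {case_id} exceeds the object class count")
    return objects[case_id - 2], objects[case_id - 1]


def select_threshold(
    sdd: SlopeDifferenceDistribution,
    real_peaks: list[int],
    request: ThresholdRequest,
    smoothed: np.ndarray,
    raw: np.ndarray | None = None,
) -> ThresholdResult:
    """Pick the threshold for the requested separation case.

    The background class is the real peak nearest the mode of the
    smoothed histogram (the background dominates the pixel count).  Among
    the SDD valleys strictly between the two class peaks bounding the
    requested case, the one with the most negative ``s`` is the
    threshold.
    """
    if len(real_peaks) != request.class_count:
        raise ParameterError("real_peaks must hold class_count entries")
    mode = int(np.argmax(smoothed))
    background = min(real_peaks, key=lambda p: abs(p - mode))
    lo, hi = _case_interval(real_peaks, background, request.case_id)
    inside = [(p, m) for p, m in sdd.valleys if lo < p < hi]
    if not inside:
        raise ThresholdSelectionError(
            f"no SDD valley strictly between the class peaks {lo} and {hi}",
            {"peaks": sdd.peaks, "valleys": sdd.valleys},
        )
    valley = min(inside, key=lambda pm: pm[1])
    return ThresholdResult(
        threshold=int(valley[0]),
        real_peaks=list(real_peaks),
        chosen_valley=(int(valley[0]), float(valley[1])),
        sdd=sdd,
        smoothed_histogram=np.asarray(smoothed, dtype=float),
        raw_histogram=np.asarray(raw, dtype=float) if raw is not None else np.array([]),
    )


def ensure_8bit(image: np.ndarray) -> np.ndarray:
    """Bring an image into integer [0, 255] range.

    Images whose values are already integers in [0, 255] pass through
    unchanged so that their histogram bins keep their native gray
    levels; anything else is rescaled so its maximum maps to 255.
    """
    image = np.asarray(image)
    as_float = image.astype(float)
    if (
        image.size
        and as_float.min() >= 0
        and as_float.max() <= 255
        and np.all(as_float == np.floor(as_float))
    ):
        return as_float.astype(np.int64)
    return rescale_to_255(image)


def threshold_image(image: np.ndarray, request: ThresholdRequest) -> ThresholdResult:
    """Full threshold selection for one image.

    Brings the image into 8-bit range, builds the normalised histogram,
    DFT-smooths it, computes the SDD and returns the threshold for the
    requested case.
    """
    rescaled = ensure_8bit(image)
    raw = normalized_histogram(rescaled)
    smoothed = dft_lowpass(raw, request.bandwidth)
    sdd = slope_difference(smoothed, request.fit_points)
    real_peaks = select_real_peaks(sdd, request.class_count)
    return select_threshold(sdd, real_peaks, request, smoothed, raw)
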