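"""End-to-end segmentation + quantification pipeline.

Stage order: rescale -> Sobel gradient -> threshold selection on the
intensity and gradient histograms -> binarize both -> case union ->
optional noise blob filter -> optional boundary smoothing filter ->
iterative-erosion quantification -> centroids.  The pipeline is a pure
function of (image, config): re-running it on the same input yields
bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError, SegquantError
from .filters import noise_blob_filter, smooth_mask
from .gradient import sobel_gradient
from .quantify import QuantificationResult, quantify
from .sdd import ThresholdRequest, ThresholdResult, ensure_8bit, threshold_image
from .union_seg import UnionCase, binarize, union_masks


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of one pipeline run.

    ``intensity`` and ``gradient`` carry the calibrated (N, W) and the
    class/case settings for the two threshold selections; ``union_case``
    picks the Boolean combination; the optional filters are enabled by
    default.  ``shape_noise_threshold`` and ``area_threshold`` default to
    their data-driven estimates when ``None``.
    """

    intensity: ThresholdRequest = field(default_factory=ThresholdRequest)
    gradient: ThresholdRequest = field(default_factory=ThresholdRequest)
    union_case: UnionCase = field(default_factory=UnionCase)
    noise_filter: bool = True
    noise_filter_repeats: int = 3
    boundary_filter: bool = True
    shape_noise_threshold: float | None = None
    boundary_bandwidth: int = 10
    pre_erosions: int = 6
    area_threshold: float | None = None


@dataclass(frozen=True)
class PipelineResult:
    """Quantification output plus every intermediate stage."""

    rescaled: np.ndarray
    gradient_image: np.ndarray
    intensity_threshold: ThresholdResult
    gradient_threshold: ThresholdResult
    intensity_mask: np.ndarray
    gradient_mask: np.ndarray
    union_mask: np.ndarray
    filtered_mask: np.ndarray
    quantification: QuantificationResult

    @property
    def centroids(self) -> list[tuple[float, float]]:
        return self.quantification.centroids


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, SegquantError):
                raise type(exc)(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(image: np.ndarray, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full framework on a 2-D grayscale image."""
    config = config or PipelineConfig()
    image = np.asarray(image)
    if image.ndim != 2:
        raise ParameterError(
            f"expected a single-channel 2-D image, got shape {image.shape}; "
            "convert multi-channel input to gray first"
        )
    with _stage("rescale"):
        rescaled = ensure_8bit(image)
    with _stage("gradient"):
        grad = sobel_gradient(rescaled)
        grad_rescaled = ensure_8bit(grad)
    with _stage("intensity threshold"):
        t0 = threshold_image(rescaled, config.intensity)
    with _stage("gradient threshold"):
        t1 = threshold_image(grad_rescaled, config.gradient)
    with _stage("binarize"):
        s_i = binarize(rescaled, t0.threshold, config.union_case.polarity)
        s_g = binarize(grad_rescaled, t1.threshold, "bright")
    with _stage("union"):
        s_u = union_masks(s_i, s_g, config.union_case)
    filtered = s_u
    if config.noise_filter:
        with _stage("noise blob filter"):
            filtered = noise_blob_filter(filtered, config.noise_filter_repeats)
    if config.boundary_filter:
        with _stage("boundary filter"):
            filtered = smooth_mask(
                filtered,
                shape_noise_threshold=config.shape_noise_threshold,
                bandwidth=config.boundary_bandwidth,
            )
    with _stage("quantify"):
        quant = quantify(
            filtered,
            area_threshold=config.area_threshold,
            pre_erosions=config.pre_erosions,
        )
    return PipelineResult(
        rescaled=rescaled,
        gradient_image=grad_rescaled,
        intensity_threshold=t0,
        gradient_threshold=t1,
        intensity_mask=s_i,
        gradient_mask=s_g,
        union_mask=s_u,
        filtered_mask=filtered,
        quantification=quant,
    )


def with_calibrated(config: PipelineConfig, which: str, fit_points: int,
                    bandwidth: int) -> PipelineConfig:
    """Return a config with calibrated (N, W) written into one threshold."""
    if which not in ("intensity", "gradient"):
        raise ParameterError("which must be 'intensity' or 'gradient'")
    req = getattr(config, which)
    new_req = replace(req, fit_points=fit_points, bandwidth=bandwidth)
    return replace(config, **{which: new_req})
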