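"""Binarization and the three-case union of intensity and gradient masks.

Two binary segmentations enter the union: ``S_I``, the intensity image
thresholded at ``T0``, and ``S_g``, the gradient image thresholded at
``T1`` (a constraint-edge mask).  Which Boolean combination is the right
segmentation depends on the image type and is a user decision:

* Case 1 — cells with many touching/overlapping boundaries that are not
  closed per cell: ``S_u = S_I and not S_g`` (most cell images).
* Case 2 — closed per-cell boundaries (e.g. many muscle-fiber images):
  ``S_u = not S_g``; the intensity mask is unused.
* Case 3 — little touching or overlap: ``S_u = S_I`` alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, ParameterError


@dataclass(frozen=True)
class UnionCase:
    """Which Boolean combination to use, and the intensity polarity.

    ``polarity`` is ``"bright"`` when cells sit above the intensity
    threshold and ``"dark"`` when they sit below it (dark cells on a
    bright background).
    """

    case_id: int = 1
    polarity: str = "bright"

    def __post_init__(self) -> None:
        if self.case_id not in (1, 2, 3):
            raise ParameterError(f"case_id must be 1, 2 or 3, got {self.case_id}")
        if self.polarity not in ("bright", "dark"):
            raise ParameterError("polarity must be 'bright' or 'dark'")


def binarize(image: np.ndarray, threshold: float, polarity: str = "bright") -> np.ndarray:
    """Threshold an image: foreground where ``value >= T``.

    With ``polarity='dark'`` the comparison is inverted
    (``value < T``) so that dark cells on a bright background become
    foreground.
    """
    if not 0 <= threshold <= 255:
        raise ParameterError(f"threshold must be in [0, 255], got {threshold}")
    image = np.asarray(image)
    if polarity == "dark":
        return image < threshold
    return image >= threshold


def union_masks(s_i: np.ndarray, s_g: np.ndarray, case: UnionCase) -> np.ndarray:
    """Combine the intensity and gradient masks for the given case."""
    s_i = np.asarray(s_i, dtype=bool)
    s_g = np.asarray(s_g, dtype=bool)
    if s_i.shape != s_g.shape:
        raise DimensionError(f"mask shapes differ: {s_i.shape} vs {s_g.shape}")
    if case.case_id == 1:
        return s_i & ~s_g
    if case.case_id == 2:
        return ~s_g
    return s_i.copy()
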