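"""Quantification scoring: per-cell TP/FP/FN against a ground-truth mask.

Each ground-truth cell region is classified by the number of identified
cell centres falling inside it: exactly one is a true positive, more
than one a false positive (over-segmentation of that cell), none a false
negative (missed cell).  Every truth cell lands in exactly one class, so
the three counts sum to the truth-cell count.  A centre is "inside" a
region when the truth label at its nearest pixel is that region's label;
identified centres in the background belong to no region and do not
enter the rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, DimensionError
from .quantify import QuantificationResult
from .synth import GroundTruth


@dataclass(frozen=True)
class QuantScore:
    """TP/FP/FN rates (percent of truth cells) and the assignment table."""

    tp_rate: float
    fp_rate: float
    fn_rate: float
    assignments: dict[int, int]  # truth label -> identified-centre count

    @property
    def n_truth(self) -> int:
        return len(self.assignments)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "truth_id": list(self.assignments),
                "centres_inside": list(self.assignments.values()),
            }
        )


def score_quantification(
    result: QuantificationResult, truth: GroundTruth
) -> QuantScore:
    """Score identified cell centres against a ground-truth label mask."""
    labels = np.asarray(truth.labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise DegenerateInputError("ground truth holds no cells")
    counts = {int(lab): 0 for lab in ids}
    h, w = labels.shape
    for r, c in result.centroids:
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < h and 0 <= ci < w):
            raise DimensionError(f"centroid ({r}, {c}) outside the truth mask")
        lab = int(labels[ri, ci])
        if lab > 0:
            counts[lab] += 1
    n = len(counts)
    tp = sum(1 for v in counts.values() if v == 1)
    fp = sum(1 for v in counts.values() if v > 1)
    fn = sum(1 for v in counts.values() if v == 0)
    return QuantScore(
        tp_rate=100.0 * tp / n,
        fp_rate=100.0 * fp / n,
        fn_rate=100.0 * fn / n,
        assignments=counts,
    )
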