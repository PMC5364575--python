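"""Edge enhancement: gradient-magnitude image via the Sobel operator.

The gradient image ``I_g = sqrt(I_x^2 + I_y^2)`` is the second input to the
threshold-selection stage; its histogram is thresholded exactly like the
intensity histogram.  The classic integer Sobel kernels are used without the
1/8 normalisation: the gradient image is rescaled to [0, 255] from its own
maximum before thresholding, so the absolute kernel scale is irrelevant.
Borders are replicate-padded to avoid spurious strong edges along the image
frame.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import DimensionError

# Row-direction derivative kernel; the column kernel is its transpose.
_SOBEL = np.array([[1, 0, -1], [2, 0, -2], [1, 0, -1]], dtype=float)


def sobel_gradient(image: np.ndarray) -> np.ndarray:
    """Gradient-magnitude image of a 2-D grayscale image.

    Parameters
    ----------
    image
        2-D array of intensities, at least 3x3.

    Returns
    -------
    ndarray of float, same shape, all values >= 0.  Zero everywhere for a
    constant input.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise DimensionError(f"expected a 2-D image, got ndim={image.ndim}")
    if image.shape[0] < 3 or image.shape[1] < 3:
        raise DimensionError(
            f"image {image.shape} smaller than the 3x3 Sobel kernel"
        )
    gx = ndimage.correlate(image, _SOBEL, mode="nearest")
    gy = ndimage.correlate(image, _SOBEL.T, mode="nearest")
    return np.hypot(gx, gy)
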