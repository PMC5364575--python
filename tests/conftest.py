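import numpy as np
import pytest

from segquant.synth import CellFieldSpec, ThreeClassSpec, make_cell_field, make_three_class


@pytest.fixture(scope="session")
def three_class():
    """Noise-free three-class image (gray 50/120/220) with its truth."""
    return make_three_class(ThreeClassSpec())


@pytest.fixture(scope="session")
def cell_field():
    """Default synthetic cell field: 20 cells, 4 touching pairs, threads,
    roughness and holes."""
    spec = CellFieldSpec(seed=0)
    img, truth = make_cell_field(spec)
    return spec, img, truth


def random_blob_mask(rng, shape=(48, 48), n_blobs=(1, 4), radius=(2, 8)):
    """Union of random filled disks — a generic hole-free test mask."""
    m = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for _ in range(rng.integers(*n_blobs)):
        r0, c0 = rng.integers(radius[1], shape[0] - radius[1], 2)
        rad = rng.integers(*radius)
        m |= (yy - r0) ** 2 + (xx - c0) ** 2 <= rad**2
    return m
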