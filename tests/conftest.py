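import numpy as np
import pytest

from oartmotion.geometry import BinaryMask, ImageGrid, ScalarVolume
from oartmotion.phantom import PhantomSpec, generate_cohort


@pytest.fixture
def unit_grid():
    """20^3 grid at 1 mm spacing, origin at 0."""
    return ImageGrid(origin=(0, 0, 0), spacing=(1, 1, 1), size=(20, 20, 20))


@pytest.fixture
def sphere_mask():
    """Digitized sphere of radius 10 mm, 1 mm spacing, centered in a 24^3 grid."""
    grid = ImageGrid(origin=(-11.5, -11.5, -11.5), spacing=(1, 1, 1), size=(24, 24, 24))
    xs, ys, zs = grid.coordinate_arrays()
    return BinaryMask(grid, xs**2 + ys**2 + zs**2 <= 10.0**2)


def ball(grid: ImageGrid, center, radius) -> BinaryMask:
    xs, ys, zs = grid.coordinate_arrays()
    c = np.asarray(center, float)
    return BinaryMask(
        grid, (xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2 <= radius**2
    )


def random_blob_pair(rng: np.random.Generator, n: int = 16):
    """Two overlapping random smoothed blobs on a small common grid."""
    from scipy.ndimage import gaussian_filter

    grid = ImageGrid(origin=(0, 0, 0), spacing=(1.5, 1.5, 2.0), size=(n, n, n))
    masks = []
    while len(masks) < 2:
        f = gaussian_filter(rng.normal(size=(n, n, n)), sigma=2.5)
        m = f > np.percentile(f, 75)
        if m.any():
            masks.append(BinaryMask(grid, m))
    return masks[0], masks[1]


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale phantom conditions for unit tests: smaller grid/organ so a
    fraction generates in well under a second; clinical rates unchanged."""
    return PhantomSpec.for_protocol(
        "empty", n_fractions=2, seed=11, grid_size=(64, 64, 48), include_dose=False
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec, "P01")


@pytest.fixture(scope="session")
def small_fraction(small_cohort):
    return small_cohort[0]
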