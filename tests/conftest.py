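import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from sphereseg.geometry import ProjectionCenter, ProjectionGeometry
from sphereseg.images import BinaryMask, PlanarImage


@pytest.fixture
def default_geometry() -> ProjectionGeometry:
    return ProjectionGeometry()


@pytest.fixture
def small_geometry() -> ProjectionGeometry:
    """Reduced grids for fast integration tests."""
    return ProjectionGeometry(planar_grid_size=96, spherical_grid_size=128)


@pytest.fixture
def image_center(default_geometry) -> ProjectionCenter:
    c = (default_geometry.planar_grid_size - 1) / 2.0
    return ProjectionCenter(c, c)


def smooth_image(seed: int, n: int = 192, sigma: float = 4.0) -> PlanarImage:
    """Band-limited random field on [0, 1] — a 'smooth phantom'."""
    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.normal(size=(n, n)), sigma)
    img = (img - img.min()) / (img.max() - img.min())
    return PlanarImage(img)


def disk_mask(n: int = 96, center=(40.0, 52.0), radius: float = 18.0) -> BinaryMask:
    ax = np.arange(n)
    rr, cc = np.meshgrid(ax, ax, indexing="ij")
    disk = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return BinaryMask(disk.astype(np.uint8))


@pytest.fixture
def phantom_case_small():
    from sphereseg.experiments import scaled_phantom_spec
    from sphereseg.phantom import generate_phantom

    return generate_phantom(scaled_phantom_spec(96, seed=42))
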