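import numpy as np
import pytest

from ctradiomics.imaging_io import CtVolume, SegmentationMask
from ctradiomics.preprocessing import IsotropicRoi, quantize_equal_probability
from ctradiomics.synthetic_cohort import SyntheticCohortConfig, generate_cohort


def digital_ball(radius_vox: float, shape=None) -> np.ndarray:
    """Binary ball of the given radius (voxels), centred in the grid."""
    if shape is None:
        n = int(2 * radius_vox) + 5
        shape = (n, n, n)
    c = [(s - 1) / 2.0 for s in shape]
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij", sparse=True)
    acc = sum(((g - cc) ** 2) for g, cc in zip(grids, c))
    return acc <= radius_vox**2


def digital_ellipsoid(radii_vox, shape=None) -> np.ndarray:
    if shape is None:
        shape = tuple(int(2 * r) + 5 for r in radii_vox)
    c = [(s - 1) / 2.0 for s in shape]
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij", sparse=True)
    acc = sum(((g - cc) / r) ** 2 for g, cc, r in zip(grids, c, radii_vox))
    return acc <= 1.0


def random_roi(rng, shape=(12, 11, 9), full_mask=False) -> IsotropicRoi:
    """Continuous-valued ROI with a blobby random mask."""
    intensities = rng.normal(0.0, 50.0, size=shape)
    if full_mask:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = digital_ellipsoid(
            (shape[0] * 0.42, shape[1] * 0.42, shape[2] * 0.42), shape
        )
    return IsotropicRoi(intensities, mask, 1.0)


def small_quantized(rng, g=4, shape=(5, 5, 4)):
    """Small QuantizedRoi with random levels for oracle comparisons."""
    roi = IsotropicRoi(rng.normal(size=shape), rng.random(shape) < 0.8, 1.0)
    return quantize_equal_probability(roi, g)


@pytest.fixture(scope="session")
def tiny_cohort_config():
    return SyntheticCohortConfig(
        n_subjects=6,
        seed=11,
        image_shape=(28, 28, 22),
        tumor_radius_mm_by_class=((5.0, 8.0), (5.0, 8.0)),
        n_genes=50,
        n_signature_genes=5,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cohort_config):
    return generate_cohort(tiny_cohort_config)


@pytest.fixture(scope="session")
def one_subject(tiny_cohort):
    return tiny_cohort[0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ball_volume_mask():
    labels = digital_ball(10.0)
    vol = CtVolume(
        np.where(labels, 40.0, -800.0) + 0.0, (1.0, 1.0, 1.0)
    )
    return vol, SegmentationMask(labels, (1.0, 1.0, 1.0))
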