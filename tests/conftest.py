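import numpy as np
import pytest

from chpmetrics.image_io import BinaryMask, VolumeImage
from chpmetrics.synthetic import PhantomSpec, generate_cohort


def mask_from(data, affine=None) -> BinaryMask:
    """Wrap a boolean/0-1 array as a mask on an identity 1 mm grid."""
    data = np.asarray(data)
    return BinaryMask(
        data=data.astype(np.uint8),
        affine=np.eye(4) if affine is None else affine,
    )


def volume_from(data, affine=None) -> VolumeImage:
    return VolumeImage(
        data=np.asarray(data, dtype=float),
        affine=np.eye(4) if affine is None else affine,
    )


def random_mask(rng, shape=(16, 16, 16), p=0.3) -> BinaryMask:
    return mask_from(rng.random(shape) < p)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A shrunken phantom for fast tests: same model, smaller geometry."""
    return PhantomSpec(
        n_subjects=5,
        seed=11,
        grid_shape=(64, 64, 64),
        ventricle_centers_mm=((-11.0, 0.0, 0.0), (11.0, 0.0, 0.0)),
        ventricle_radii_mm=(8.0, 18.0, 9.0),
        chp_thickness_mm=2.2,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)
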