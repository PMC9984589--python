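import numpy as np
import pytest

from segrepeat import (
    LabelVolume,
    NoiseModel,
    PhantomSpec,
    make_phantom,
    simulate_repeats,
)


@pytest.fixture(scope="session")
def cylinder_spec():
    """A straight 100 mm x r15 mm tube on the clinical-like grid."""
    return PhantomSpec(
        muscle_kind="straight_tube", length_mm=100.0, max_radius_mm=15.0,
        taper=0.0, pixel_mm=0.8, slice_mm=4.0, seed=11,
    )


@pytest.fixture(scope="session")
def cylinder_study(cylinder_spec):
    return make_phantom(cylinder_spec)


@pytest.fixture(scope="session")
def noisy_repeats(cylinder_study):
    """Three extremity-weighted noisy re-segmentations of the cylinder."""
    noise = NoiseModel(belly_sigma_mm=0.5, extremity_sigma_mm=3.0,
                       correlation_length_mm=8.0, seed=5)
    return simulate_repeats(cylinder_study.truth, cylinder_study.true_axis, noise, 3)


def random_blob(rng, shape=(24, 24, 24), spacing=(1.0, 1.2, 2.0)) -> LabelVolume:
    """A random smooth connected blob for oracle tests."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=4.0)
    mask = field > np.quantile(field, 0.75)
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = rng.uniform(-10, 10, 3)
    return LabelVolume(mask.astype(np.uint8), affine)
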