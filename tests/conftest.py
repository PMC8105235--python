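"""Shared fixtures: a small, fast phantom and its ground truth."""

import dataclasses

import numpy as np
import pytest

from fpact.phantom import PhantomSpec, build_ground_truth


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Coarse-voxel swine phantom for fast unit tests (same anatomy)."""
    return PhantomSpec(
        grid_shape=(48, 48, 48),
        spacing_mm=(0.9, 0.9, 1.0),
        center_mm=(21.6, 21.6, 36.0),
        aorta_center_mm=(21.6, 21.6, 42.0),
        noise_sigma_ref_hu=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return build_ground_truth(small_spec)


@pytest.fixture()
def noiseless_small(small_spec):
    return dataclasses.replace(small_spec, noise_sigma_ref_hu=0.0)


def slab_mask(shape=(20, 12, 6)):
    """A solid rectangular slab mask on a unit-spacing grid."""
    from fpact.volume import BinaryMask

    return BinaryMask(np.ones(shape, dtype=bool), (1.0, 1.0, 1.0))
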