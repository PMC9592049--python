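import numpy as np
import pytest

from srdenoise import (
    AcquisitionParams,
    acquire_stack,
    make_answer,
    make_granule_phantom,
    make_nuclei_phantom,
)
from srdenoise.phantom import PhantomParams


def small_params(seed: int, size: int = 64, n_objects: int = 24) -> PhantomParams:
    """Default phantom geometry rescaled to a fast test size."""
    return PhantomParams(image_size=512, n_objects=n_objects, seed=seed).scaled_to(size)


def make_batches(base_seed: int, n_batches: int = 6, size: int = 64, n_frames: int = 16, modality: str = "3pf"):
    """Simulated acquisition batches at the scaled-down study conditions."""
    maker = make_nuclei_phantom if modality == "3pf" else make_granule_phantom
    batches = []
    for b in range(n_batches):
        clean = maker(small_params(base_seed * 100 + b, size=size))
        acq = AcquisitionParams(n_frames=n_frames, seed=base_seed * 100 + 50 + b)
        stack = acquire_stack(clean, acq)
        batches.append((stack, make_answer(stack)))
    return batches


@pytest.fixture(scope="session")
def nuclei_clean():
    return make_nuclei_phantom(small_params(11))


@pytest.fixture(scope="session")
def granule_clean():
    return make_granule_phantom(small_params(12))


@pytest.fixture(scope="session")
def nuclei_batch(nuclei_clean):
    stack = acquire_stack(nuclei_clean, AcquisitionParams(n_frames=16, seed=21))
    return stack, make_answer(stack)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
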