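import numpy as np
import pytest

from vnetpp.brats_io import preprocess_case
from vnetpp.synthetic import TEST_SHAPE, PhantomConfig, generate_phantom_case

#: phantom settings shared by training / evaluation / acceptance tests:
#: high contrast, low noise, generous tumors -> learnable at tiny scale
OVERFIT_PHANTOM = dict(
    shape=TEST_SHAPE,
    noise_sd=0.02,
    tumor_fraction_range=(0.10, 0.15),
)


def make_phantom_slices(seed: int, n_cases: int = 2, window=(6, 10), crop_to: int = 64):
    cfg = PhantomConfig(n_cases=n_cases, seed=seed, **OVERFIT_PHANTOM)
    slices = []
    for i in range(n_cases):
        slices += preprocess_case(
            generate_phantom_case(cfg, i), slice_window=window, crop_to=crop_to
        )
    return slices


@pytest.fixture(scope="session")
def phantom_slices_64():
    """8 preprocessed 64x64x4 phantom slices (2 cases x 4 axial slices)."""
    return make_phantom_slices(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
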