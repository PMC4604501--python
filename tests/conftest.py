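import dataclasses
import logging

import numpy as np
import pytest

from serscal import (
    NoiseConfig,
    default_components,
    make_wavenumber_grid,
    mixture_design,
    preprocess_set,
    simulate_dataset,
)
from serscal.simulate import NOISELESS

logging.getLogger("serscal").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def grid():
    """The default instrument grid: 1024 channels, 200-3400 cm^-1."""
    return make_wavenumber_grid(200, 3400, 1024)


@pytest.fixture(scope="session")
def small_grid():
    """Coarse grid for fast network tests; all default bands still fit."""
    return make_wavenumber_grid(200, 3400, 256)


@pytest.fixture(scope="session")
def linear_components():
    """Default analytes with linear responses (no caffeine saturation)."""
    return tuple(
        dataclasses.replace(c, saturation_conc=None) for c in default_components()
    )


@pytest.fixture(scope="session")
def noisefree_small_dataset(small_grid, linear_components):
    """Exact linear-mixing dataset: 21 compositions x 2 replicates, 256 ch."""
    return simulate_dataset(
        design=mixture_design(3, 0.2),
        replicates=2,
        components=linear_components,
        noise=NOISELESS,
        seed=11,
        grid=small_grid,
    )


@pytest.fixture(scope="session")
def noisefree_small_preprocessed(noisefree_small_dataset):
    return preprocess_set(noisefree_small_dataset.spectra)
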