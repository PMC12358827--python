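import numpy as np
import pytest

from nanospot import AssayConfig, make_ground_truth, render_chip_images
from nanospot.synth import render_membrane_images


@pytest.fixture
def small_config():
    """12 x 12 lattice, deterministic, default noise levels."""
    return AssayConfig(n_rows=12, n_cols=12, n_cells=30, seed=1)


@pytest.fixture
def noiseless_config():
    return AssayConfig(
        n_rows=12, n_cols=12, n_cells=30, seed=1,
        noise_sd=0.0, membrane_noise_sd=0.0, intensity_cv=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def rendered_assay(small_config):
    """Truth + layout + chip stack + membrane pair for the small chip."""
    truth, layout = make_ground_truth(small_config)
    chip = render_chip_images(truth, layout, small_config)
    imprint, psa, transform = render_membrane_images(truth, layout, small_config)
    return small_config, truth, layout, chip, imprint, psa, transform
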