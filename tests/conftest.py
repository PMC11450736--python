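import numpy as np
import pytest

from sevenq import AssayDesign, PopulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_assay():
    """A small, fast assay condition: few ROIs, no background."""
    return AssayDesign(n_roi=3, bg_density_per_um2=0.0)


@pytest.fixture
def default_population():
    return PopulationConfig()


def make_blob(rng, center, n, sd_nm=25.0):
    """A tight Gaussian cluster of localizations, vesicle-sized."""
    return np.asarray(center, float) + rng.normal(0.0, sd_nm, size=(n, 2))
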