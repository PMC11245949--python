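import numpy as np
import pytest

import nirferm as nf


@pytest.fixture(scope="session")
def small_benchmark():
    """A 126-profile benchmark (full design grid, 3 profiles per sample)."""
    return nf.make_benchmark(nf.small_scenario(seed=42))


@pytest.fixture(scope="session")
def small_absorbance(small_benchmark):
    """Preprocessed spectra (absorbance + SG smoothing) of the benchmark."""
    spectra = nf.reflectance_to_absorbance(small_benchmark.spectra)
    return nf.sg_smooth(spectra)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
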