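import numpy as np
import pytest

from quadstruct import (
    SynthConfig,
    build_ideal_gq,
    c9_22mer,
    detect_tetrads,
    gen_basis_spectra,
)


@pytest.fixture(scope="session")
def basis():
    return gen_basis_spectra(SynthConfig(seed=0))


@pytest.fixture(scope="session")
def ideal_ap():
    """Idealized antiparallel quadruplex of the 22-mer (built once)."""
    return build_ideal_gq(c9_22mer(), topology="antiparallel")


@pytest.fixture(scope="session")
def ideal_p():
    return build_ideal_gq(c9_22mer(), topology="parallel")


@pytest.fixture(scope="session")
def ap_tetrads(ideal_ap):
    return detect_tetrads(ideal_ap)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
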