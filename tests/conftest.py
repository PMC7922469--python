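import warnings

import numpy as np
import pytest

from soynmr import (
    bin_spectra,
    build_metabolite_library,
    default_design,
    simulate_cohort,
    simulate_spectra,
)

# NIPALS may legitimately hit max_iter on permuted degenerate responses
warnings.filterwarnings("ignore", message="NIPALS reached max_iter")

COHORT_SEED = 11


@pytest.fixture(scope="session")
def library():
    return build_metabolite_library()


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def cohort(design):
    return simulate_cohort(design, COHORT_SEED)


@pytest.fixture(scope="session")
def spectra(design):
    return simulate_spectra(design, COHORT_SEED)


@pytest.fixture(scope="session")
def binned(spectra):
    return bin_spectra(spectra)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
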