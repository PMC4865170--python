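import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from promdissect import StudyConfig, generate_study
from promdissect.catalog import default_catalogue

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

#: The printed 97 nt artificial promoter P2.3 (one palindromic FNR site at
#: [31,45), the AATAAAC initiation motif at [83,90)).
P23 = (
    "AGACCAATGG" "ACATCCACGG" "CGATTATTAC" "GTTGATCATG" "ATCAAGCAGT"
    "TTTAAGACTA" "TACCAACTTG" "ATTTAATTCT" "TGTAATAAAC" "GAATGCC"
)


@pytest.fixture(scope="session")
def p23():
    return P23


@pytest.fixture(scope="session")
def study():
    """One default-shaped synthetic study (background scaled for speed)."""
    return generate_study(StudyConfig(seed=1, n_rp=200, genome_length=100_000))


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
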