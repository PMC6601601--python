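import numpy as np
import pytest

from amplisnp import DEFAULT_DESIGN, CohortConfig, simulate_cohort
from amplisnp.simulate import HaplotypeFreqs

# Study-scale haplotype structure (TA, TG, CA, CG)
STUDY_FREQS = HaplotypeFreqs(0.5485, 0.0216, 0.0286, 0.4013)


@pytest.fixture(scope="session")
def design():
    return DEFAULT_DESIGN


@pytest.fixture(scope="session")
def snp1(design):
    return design.snps[0]


@pytest.fixture(scope="session")
def snp2(design):
    return design.snps[1]


@pytest.fixture(scope="session")
def small_cohort():
    """An 80-subject synthetic cohort reused across read-only tests."""
    return simulate_cohort(CohortConfig(n_case=40, n_control=40), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
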