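import pytest

import threatdecode as td

CONTRAST = td.Contrast("conditioning", 1, "CSplus")


@pytest.fixture(scope="session")
def small_atlas():
    return td.generate_synthetic_atlas((16, 16, 16), n_circuit=10, n_extended=14, seed=7)


@pytest.fixture(scope="session")
def community_cohort(small_atlas):
    coding = td.three_community_coding(small_atlas, delta=2.5)
    data = td.generate_beta_dataset(60, small_atlas, coding, seed=21)
    return data, coding


@pytest.fixture(scope="session")
def signal_cohort():
    """Gridless paired cohort with a strong planted effect."""
    return td.paired_cohort(120, 40, delta=2.0, seed=5, n_signal=10)


@pytest.fixture(scope="session")
def null_cohort():
    return td.paired_cohort(80, 40, delta=0.0, seed=9)


@pytest.fixture
def contrast():
    return CONTRAST


@pytest.fixture
def fast_cv():
    return td.CVConfig(repeats=2, grid=(1.0,), seed=0)
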