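import pytest

from mosaiclone.datasets import (
    monoclonal_cohort,
    mosaic_toy_matrix,
    patient2_like_cohort,
    reappearing_cna_matrix,
)


@pytest.fixture
def toy_matrix():
    return mosaic_toy_matrix()


@pytest.fixture
def monoclonal_matrix():
    return monoclonal_cohort()


@pytest.fixture
def reappearing_matrix():
    return reappearing_cna_matrix()


@pytest.fixture(scope="session")
def patient2_like():
    return patient2_like_cohort()
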