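"""Shared fixtures: small seeded synthetic datasets built at test time."""

import logging

import pytest

from omigrow import generate_design, generate_omics
from omigrow.preprocess import standardize

logging.getLogger("omigrow").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def design14():
    return generate_design(14, seed=11)


@pytest.fixture(scope="session")
def small_omics(design14):
    """Paired 14 x 40 layers with 4 planted drivers, mild noise."""
    return generate_omics(
        design14, n_features=40, n_planted=4, coupling=0.8, noise_sd=0.05, seed=11
    )


@pytest.fixture(scope="session")
def small_prot_std(small_omics):
    _, prot, rates, _ = small_omics
    return standardize(prot), rates
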