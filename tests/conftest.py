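import warnings

import pytest

from butycore.pipeline import _community_profiles
from butycore.screen import TaxonProfileSet
from butycore.synth import (
    SimulationConfig,
    make_community,
    reference_catalogue,
    simulate_counts,
)


@pytest.fixture(scope="session")
def community():
    return make_community(12, seed=11)


@pytest.fixture(scope="session")
def catalogue(community):
    return reference_catalogue(community, seed=12, decoy_taxa=1)


@pytest.fixture(scope="session")
def taxon_profiles(community):
    return TaxonProfileSet(_community_profiles(community))


@pytest.fixture(scope="session")
def sample_counts(community, catalogue):
    return simulate_counts(
        community, catalogue, SimulationConfig(depth=200_000, seed=13, n_samples=3)
    )


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
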