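from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import phyllotig as pt

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_db():
    """A 10-taxon 16S reference set shared across tests."""
    return pt.generate_reference_db(n_taxa=10, seed=3)


@pytest.fixture(scope="session")
def curated_db(reference_db):
    return pt.curate_reference_db([t.as_ssu_record() for t in reference_db])


@pytest.fixture(scope="session")
def community(reference_db):
    """The default synthetic community (study conditions, seed 3)."""
    config = pt.CommunityConfig(seed=3, n_taxa=10, n_contigs=40)
    return pt.generate_community(config, reference_db)


@pytest.fixture(scope="session")
def species_level_community(reference_db):
    """A community whose 16S copies all sit at species-level identity,
    for planted-abundance recovery checks."""
    config = pt.CommunityConfig(
        seed=11, n_taxa=10, n_contigs=30, divergence_levels=(99.5, 98.5, 97.5)
    )
    return pt.generate_community(config, reference_db)
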