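"""Shared fixtures: small hand-built objects and one mid-size community.

Everything is generated programmatically; the session-scoped community
fixtures are shared across modules so the 100-run Louvain iteration is
paid once.
"""

import pytest

from proxibin import (
    CommunitySpec,
    Contig,
    ContigCatalog,
    build_network,
    core_communities,
    iterate_louvain,
    normalize_network,
    simulate_community,
    simulate_pairs,
)


@pytest.fixture
def small_catalog():
    return ContigCatalog(
        [
            Contig("c1", 1000, 4.0),
            Contig("c2", 2000, 9.0),
            Contig("c3", 1500, 1.0),
            Contig("c4", 800, 2.5),
        ]
    )


@pytest.fixture(scope="session")
def community():
    """Default 10-genome community with alignment noise, plus its truth."""
    spec = CommunitySpec(seed=42, noise_frac=0.1)
    catalog, truth = simulate_community(spec)
    return spec, catalog, truth


@pytest.fixture(scope="session")
def community_network(community):
    spec, catalog, truth = community
    pairs = simulate_pairs(catalog, truth, spec)
    return normalize_network(build_network(pairs, catalog))


@pytest.fixture(scope="session")
def community_partitions(community_network):
    """100 seeded Louvain runs on the default community network."""
    return iterate_louvain(community_network, 100, base_seed=0)


@pytest.fixture(scope="session")
def community_ccs(community, community_network, community_partitions):
    _, catalog, _ = community
    return core_communities(
        community_partitions, 100, catalog, network=community_network
    )
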