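"""Louvain iteration and core-community (partition meet) extraction."""

import itertools

import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp

from proxibin import (
    Contig,
    ContigCatalog,
    ContactNetwork,
    Partition,
    co_cluster_scores,
    core_communities,
    iterate_louvain,
    louvain_once,
)

# ------------------------------------------------------------- oracles


def modularity_oracle(graph, labels):
    """Newman–Girvan Q computed from first principles.

    Q = sum over communities c of [ w_in(c)/W_tot - (s(c)/(2*W_tot))^2 ]
    with W_tot the total edge weight, w_in(c) the weight inside c and
    s(c) the summed (weighted) degree of c's nodes.
    """
    w_tot = sum(d["weight"] for _, _, d in graph.edges(data=True))
    if w_tot == 0:
        return 0.0
    comms = {}
    for node, lab in labels.items():
        comms.setdefault(lab, set()).add(node)
    q = 0.0
    for members in comms.values():
        w_in = sum(
            d["weight"]
            for u, v, d in graph.edges(members, data=True)
            if u in members and v in members
        )
        s = sum(dict(graph.degree(members, weight="weight")).values())
        q += w_in / w_tot - (s / (2 * w_tot)) ** 2
    return q


def is_locally_optimal(graph, labels):
    """No single-node move and no pairwise community merge improves Q."""
    q0 = modularity_oracle(graph, labels)
    labs = set(labels.values())
    for node in graph.nodes:
        for target in labs | {max(labs) + 1}:
            if target == labels[node]:
                continue
            trial = dict(labels)
            trial[node] = target
            if modularity_oracle(graph, trial) > q0 + 1e-12:
                return False
    for a, b in itertools.combinations(labs, 2):
        trial = {n: (a if l == b else l) for n, l in labels.items()}
        if modularity_oracle(graph, trial) > q0 + 1e-12:
            return False
    return True


def meet_oracle(partitions, contig_ids):
    """Pairwise all-runs co-membership closure via boolean matrices."""
    ids = list(contig_ids)
    n = len(ids)
    together = np.ones((n, n), dtype=bool)
    for p in partitions:
        labs = np.array([p.labels[c] for c in ids])
        together &= labs[:, None] == labs[None, :]
    n_comp, comp = sp.csgraph.connected_components(sp.csr_matrix(together))
    groups = {}
    for cid, k in zip(ids, comp):
        groups.setdefault(k, set()).add(cid)
    return {frozenset(g) for g in groups.values()}


def random_partitions(rng, contig_ids, n_runs, n_labels=8):
    return [
        Partition(
            run_id=i,
            labels={c: int(rng.integers(n_labels)) for c in contig_ids},
            modularity=0.0,
        )
        for i in range(n_runs)
    ]


def unit_network(graph):
    cat = ContigCatalog(Contig(str(n), 1000, 1.0) for n in graph.nodes)
    g = nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes})
    for _, _, d in g.edges(data=True):
        d.setdefault("raw_count", 1)
    return ContactNetwork(cat, g, normalized=True)


# ---------------------------------------------------------------- tests


class TestLouvainOnce:
    def test_two_cliques_with_weak_bridge(self):
        g = nx.Graph()
        for offset in (0, 4):
            for a, b in itertools.combinations(range(offset, offset + 4), 2):
                g.add_edge(a, b, weight=1.0)
        g.add_edge(0, 4, weight=0.01)
        net = unit_network(g)
        for seed in range(5):
            part = louvain_once(net, seed)
            comms = {frozenset(c) for c in part.communities()}
            assert comms == {
                frozenset({"0", "1", "2", "3"}),
                frozenset({"4", "5", "6", "7"}),
            }
            assert is_locally_optimal(net.graph, part.labels)

    def test_edgeless_network_gives_singletons_q0(self):
        net = unit_network(nx.empty_graph(5))
        part = louvain_once(net, 0)
        assert len(set(part.labels.values())) == 5
        assert part.modularity == 0.0

    def test_single_clique_one_community_closed_form_q(self):
        g = nx.complete_graph(6)
        for _, _, d in g.edges(data=True):
            d["weight"] = 1.0
        net = unit_network(g)
        part = louvain_once(net, 3)
        assert len(set(part.labels.values())) == 1
        # one community holding everything: Q = w_in/W - (2W/(2W))^2 = 0
        assert part.modularity == pytest.approx(0.0, abs=1e-12)
        assert part.modularity == pytest.approx(
            modularity_oracle(net.graph, part.labels), abs=1e-12
        )

    def test_isolated_nodes_become_singletons(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=1.0)
        g.add_node(2)
        net = unit_network(g)
        part = louvain_once(net, 0)
        assert part.labels["2"] not in (part.labels["0"], part.labels["1"])

    def test_empty_network_errors(self):
        with pytest.raises(ValueError, match="empty"):
            louvain_once(ContactNetwork(ContigCatalog()), 0)

    def test_reported_modularity_matches_oracle(self, community_network):
        part = louvain_once(community_network, 7)
        assert part.modularity == pytest.approx(
            modularity_oracle(community_network.graph, part.labels), rel=1e-9
        )

    def test_beats_all_singletons_on_planted_network(self, community_network):
        """Modularity non-triviality on a planted-partition graph."""
        part = louvain_once(community_network, 0)
        singletons = {c: i for i, c in enumerate(community_network.catalog.ids)}
        assert part.modularity > modularity_oracle(community_network.graph, singletons)


class TestIterateLouvain:
    def test_single_run_equals_louvain_once_with_derived_seed(self, community_network):
        (part,) = iterate_louvain(community_network, 1, base_seed=9)
        again = louvain_once(community_network, 9)
        assert part.labels == again.labels

    def test_same_base_seed_reproduces_labels(self, community_network):
        a = iterate_louvain(community_network, 3, base_seed=5)
        b = iterate_louvain(community_network, 3, base_seed=5)
        assert [p.labels for p in a] == [p.labels for p in b]

    def test_large_cc_count_plateaus_over_prefixes(
        self, community, community_network, community_partitions
    ):
        """The >500 kb CC count stabilizes as runs accumulate."""
        _, catalog, _ = community
        counts = []
        for k in range(1, len(community_partitions) + 1):
            ccs = core_communities(community_partitions, k, catalog)
            counts.append(sum(1 for cc in ccs if cc.total_bp > 500_000))
        assert len(set(counts[-20:])) == 1


class TestCoreCommunities:
    def test_meet_of_single_partition_is_itself(self, small_catalog):
        p = Partition(0, {"c1": 0, "c2": 0, "c3": 0, "c4": 1}, 0.0)
        ccs = core_communities([p], 1, small_catalog)
        assert {cc.contig_ids for cc in ccs} == {
            frozenset({"c1", "c2", "c3"}),
            frozenset({"c4"}),
        }

    def test_hand_computed_meet(self, small_catalog):
        p1 = Partition(0, {"c1": 0, "c2": 0, "c3": 1, "c4": 1}, 0.0)
        p2 = Partition(1, {"c1": 0, "c2": 0, "c3": 0, "c4": 1}, 0.0)
        ccs = core_communities([p1, p2], 2, small_catalog)
        assert {cc.contig_ids for cc in ccs} == {
            frozenset({"c1", "c2"}),
            frozenset({"c3"}),
            frozenset({"c4"}),
        }

    def test_ids_ordered_by_decreasing_total_bp(self, small_catalog):
        p = Partition(0, {"c1": 0, "c2": 1, "c3": 2, "c4": 3}, 0.0)
        ccs = core_communities([p], 1, small_catalog)
        sizes = [cc.total_bp for cc in ccs]
        assert sizes == sorted(sizes, reverse=True)
        assert [cc.cc_id for cc in ccs] == [1, 2, 3, 4]

    def test_zero_n_use_errors(self, small_catalog):
        with pytest.raises(ValueError):
            core_communities([], 0, small_catalog)

    def test_matches_co_membership_closure_oracle(self):
        rng = np.random.default_rng(10)
        ids = [f"c{i}" for i in range(200)]
        cat = ContigCatalog(Contig(c, 1000) for c in ids)
        parts = random_partitions(rng, ids, 50)
        ccs = core_communities(parts, 50, cat)
        assert {cc.contig_ids for cc in ccs} == meet_oracle(parts, ids)

    def test_refines_every_input_partition(self):
        rng = np.random.default_rng(11)
        ids = [f"c{i}" for i in range(80)]
        cat = ContigCatalog(Contig(c, 1000) for c in ids)
        parts = random_partitions(rng, ids, 10, n_labels=4)
        ccs = core_communities(parts, 10, cat)
        for cc in ccs:
            for p in parts:
                assert len({p.labels[c] for c in cc.contig_ids}) == 1

    def test_more_runs_only_split_never_merge(self):
        rng = np.random.default_rng(12)
        ids = [f"c{i}" for i in range(80)]
        cat = ContigCatalog(Contig(c, 1000) for c in ids)
        parts = random_partitions(rng, ids, 12, n_labels=3)
        prev = None
        for k in range(1, 13):
            cur = {cc.contig_ids for cc in core_communities(parts, k, cat)}
            if prev is not None:
                for group in cur:
                    assert any(group <= old for old in prev)
            prev = cur

    def test_sub_networks_attached_and_restricted(self, small_catalog):
        g = nx.Graph()
        g.add_edge("c1", "c2", weight=1.0, raw_count=1)
        g.add_edge("c3", "c4", weight=1.0, raw_count=1)
        net = ContactNetwork(small_catalog, g, normalized=True)
        p = Partition(0, {"c1": 0, "c2": 0, "c3": 1, "c4": 1}, 0.0)
        ccs = core_communities([p], 1, small_catalog, network=net)
        for cc in ccs:
            assert set(cc.sub_network.catalog.ids) == set(cc.contig_ids)
            assert cc.sub_network.n_edges == 1


class TestCoClusterScores:
    def test_always_together_scores_n_runs(self, small_catalog):
        parts = [Partition(i, {"c1": 0, "c2": 0, "c3": 1, "c4": 1}, 0.0) for i in range(5)]
        # force a finer CC split than the runs support, via one extra run
        parts.append(Partition(5, {"c1": 0, "c2": 1, "c3": 2, "c4": 2}, 0.0))
        ccs = core_communities(parts, 6, small_catalog)
        scores = {s.pair: s.score for s in co_cluster_scores(parts, ccs)}
        by_members = {cc.contig_ids: cc.cc_id for cc in ccs}
        a = by_members[frozenset({"c1"})]
        b = by_members[frozenset({"c2"})]
        assert scores[tuple(sorted((a, b)))] == 5  # co-labeled in 5 of 6 runs

    def test_matches_brute_force_label_comparison(self):
        rng = np.random.default_rng(13)
        ids = [f"c{i}" for i in range(40)]
        cat = ContigCatalog(Contig(c, 1000) for c in ids)
        parts = random_partitions(rng, ids, 15, n_labels=3)
        ccs = core_communities(parts, 15, cat)
        scores = {s.pair: s.score for s in co_cluster_scores(parts, ccs)}
        for ca, cb in itertools.combinations(ccs, 2):
            ra, rb = next(iter(ca.contig_ids)), next(iter(cb.contig_ids))
            want = sum(1 for p in parts if p.labels[ra] == p.labels[rb])
            assert scores[tuple(sorted((ca.cc_id, cb.cc_id)))] == want
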