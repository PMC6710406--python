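"""Iterated Louvain clustering and core-community extraction.

A single Louvain run greedily maximizes weighted Newman–Girvan
modularity; its output depends on the (seeded) node visit order. Running
it many times and keeping only groups of contigs that co-cluster in
*every* retained run — the meet (common refinement) of the run
partitions — yields core communities (CCs): conservative contig pools
that are robust to the stochasticity of any single run.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx

from proxibin.catalog import ContigCatalog
from proxibin.network import ContactNetwork

DEFAULT_N_RUNS = 400
DEFAULT_N_USE = 100


@dataclass
class Partition:
    """Labeling of every catalog contig from one Louvain run.

    ``labels`` maps contig_id -> integer community label; ``modularity``
    is the weighted Newman–Girvan Q of this labeling (0 for an edgeless
    network, by convention).
    """

    run_id: int
    labels: Dict[str, int]
    modularity: float

    def communities(self) -> List[frozenset]:
        groups: Dict[int, set] = defaultdict(set)
        for cid, lab in self.labels.items():
            groups[lab].add(cid)
        return [frozenset(g) for g in groups.values()]


@dataclass
class CoreCommunity:
    """Maximal contig set co-clustered in every retained run.

    ``cc_id`` is 1-based, assigned by decreasing total bp (ties broken by
    the lexicographically smallest member id). ``sub_network`` is the
    contact network restricted to the members, when a network was given.
    """

    cc_id: int
    contig_ids: frozenset
    total_bp: int
    sub_network: Optional[ContactNetwork] = None

    def __len__(self) -> int:
        return len(self.contig_ids)


@dataclass(frozen=True)
class CoClusterScore:
    """Number of runs in which two CCs carried one common label."""

    pair: Tuple[int, int]
    score: int


def _modularity(graph: nx.Graph, communities: Sequence[set]) -> float:
    if graph.number_of_edges() == 0:
        return 0.0
    return nx.community.modularity(graph, communities, weight="weight")


def louvain_once(net: ContactNetwork, seed: int) -> Partition:
    """One seeded Louvain run on the contact network.

    Greedy modularity optimization under the weighted Newman–Girvan
    criterion (resolution 1): local node moves to the neighboring
    community with the best positive gain, then graph aggregation,
    repeated to convergence. The node visit order is a seed-determined
    permutation, so the result is reproducible per seed. Isolated nodes
    become singleton communities. Expects normalized edge weights on the
    ``weight`` attribute.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot partition an empty network")
    if net.graph.number_of_edges() == 0:
        labels = {cid: i for i, cid in enumerate(net.catalog.ids)}
        return Partition(run_id=seed, labels=labels, modularity=0.0)
    comms = nx.community.louvain_communities(net.graph, weight="weight", seed=int(seed))
    labels: Dict[str, int] = {}
    for lab, comm in enumerate(comms):
        for cid in comm:
            labels[cid] = lab
    q = _modularity(net.graph, comms)
    return Partition(run_id=seed, labels=labels, modularity=q)


def iterate_louvain(net: ContactNetwork, n_runs: int, base_seed: int) -> List[Partition]:
    """``n_runs`` independent Louvain runs with derived seeds.

    Run ``i`` uses seed ``base_seed + i``, so any individual run is
    re-creatable and a prefix of a longer iteration is identical to a
    shorter one started from the same base seed.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    parts = []
    for i in range(n_runs):
        p = louvain_once(net, base_seed + i)
        p.run_id = i
        parts.append(p)
    return parts


def core_communities(
    partitions: Sequence[Partition],
    n_use: int,
    catalog: ContigCatalog,
    network: Optional[ContactNetwork] = None,
) -> List[CoreCommunity]:
    """Meet of the first ``n_use`` partitions.

    Two contigs share a CC iff they share a community label in *all* of
    the first ``n_use`` runs; equivalently each CC is one equivalence
    class of the label-vector map contig -> (label_run1, ..., label_runN).
    CCs are ordered by decreasing total bp (ties by smallest member id)
    for 1-based id assignment; sub-networks are attached when ``network``
    is given.
    """
    if n_use == 0:
        raise ValueError("n_use must be >= 1")
    if n_use > len(partitions):
        raise ValueError(f"n_use={n_use} exceeds the {len(partitions)} available partitions")
    used = partitions[:n_use]
    groups: Dict[tuple, set] = defaultdict(set)
    for cid in catalog.ids:
        key = tuple(p.labels[cid] for p in used)
        groups[key].add(cid)
    ordered = sorted(
        groups.values(),
        key=lambda members: (-sum(catalog.length_of(c) for c in members), min(members)),
    )
    ccs = []
    for i, members in enumerate(ordered, start=1):
        total_bp = sum(catalog.length_of(c) for c in members)
        sub = network.subnetwork(members) if network is not None else None
        ccs.append(CoreCommunity(cc_id=i, contig_ids=frozenset(members), total_bp=total_bp, sub_network=sub))
    return ccs


def co_cluster_scores(
    partitions: Sequence[Partition],
    ccs: Sequence[CoreCommunity],
) -> List[CoClusterScore]:
    """For each CC pair, in how many runs were the two CCs co-labeled.

    By construction every CC is label-uniform within each run, so one
    representative member per CC suffices.
    """
    reps = {cc.cc_id: next(iter(cc.contig_ids)) for cc in ccs}
    out = []
    ids = sorted(reps)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            score = sum(1 for p in partitions if p.labels[reps[a]] == p.labels[reps[b]])
            out.append(CoClusterScore(pair=(a, b), score=score))
    return out
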