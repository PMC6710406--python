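"""Contact-network construction from proximity-ligation read-pair alignments.

The two mates of a 3C/Hi-C pair are aligned independently in single-end
mode. Pairs where both mates align unambiguously with mapping quality >=
20 to two *different* contigs become edges of an undirected contact
network: the raw weight of edge (a, b) counts the read pairs bridging a
and b, and the normalized weight divides that count by the geometric mean
of the two contigs' coverages, flattening the abundance signal so that
edge weight reflects contact propensity rather than sequencing depth.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import networkx as nx

from proxibin.catalog import ContigCatalog

DEFAULT_MIN_MAPQ = 20
DEFAULT_MIN_CONTIG_LENGTH = 500


@dataclass(frozen=True)
class AlignedRead:
    """One single-end alignment record of one mate of a read pair.

    ``mate`` is 1 or 2; ``position`` is the 0-based leftmost coordinate;
    ``ambiguous`` marks multi-mapping reads (secondary/supplementary
    records, or several primary records for the same mate).
    ``read_length`` is the number of aligned bases, used for coverage.
    """

    read_id: str
    mate: int
    contig_id: str
    position: int
    mapq: int
    ambiguous: bool = False
    read_length: int = 0

    def __post_init__(self) -> None:
        if self.mate not in (1, 2):
            raise ValueError(f"mate must be 1 or 2, got {self.mate}")
        if self.position < 0:
            raise ValueError("position must be >= 0")
        if not 0 <= self.mapq <= 60:
            raise ValueError(f"mapq must be in [0, 60], got {self.mapq}")


@dataclass
class PairingStats:
    """Per-category counts of read pairs dropped by :func:`pair_reads`."""

    emitted: int = 0
    same_contig: int = 0
    low_mapq: int = 0
    ambiguous: int = 0
    unmatched_singleton: int = 0
    duplicate: int = 0

    @property
    def total_seen(self) -> int:
        return (
            self.emitted
            + self.same_contig
            + self.low_mapq
            + self.ambiguous
            + self.unmatched_singleton
            + self.duplicate
        )

    def as_dict(self) -> Dict[str, int]:
        return {
            "emitted": self.emitted,
            "same_contig": self.same_contig,
            "low_mapq": self.low_mapq,
            "ambiguous": self.ambiguous,
            "unmatched_singleton": self.unmatched_singleton,
            "duplicate": self.duplicate,
        }


@dataclass(frozen=True)
class ContactEdge:
    """Undirected contact edge in canonical order ``contig_a < contig_b``."""

    contig_a: str
    contig_b: str
    raw_count: int
    weight: float

    def __post_init__(self) -> None:
        if self.contig_a == self.contig_b:
            raise ValueError("self-edges are excluded from the contact network")
        if self.contig_a > self.contig_b:
            raise ValueError("edge endpoints must be in canonical (sorted) order")
        if self.raw_count < 1:
            raise ValueError("raw_count must be >= 1")


class ContactNetwork:
    """Undirected weighted contact graph over a contig catalog.

    Every catalog contig is a node (contigs without inter-contig pairs
    stay as isolated nodes). Edges carry ``raw_count`` (read pairs) and
    ``weight`` (equal to the raw count until :func:`normalize_network`
    rescales it by coverage).
    """

    def __init__(
        self,
        catalog: ContigCatalog,
        graph: Optional[nx.Graph] = None,
        total_pairs_used: int = 0,
        normalized: bool = False,
    ):
        self.catalog = catalog
        if graph is None:
            graph = nx.Graph()
        self.graph = graph
        for cid in catalog.ids:
            if cid not in self.graph:
                self.graph.add_node(cid)
        for node in self.graph.nodes:
            if node not in catalog:
                raise ValueError(f"graph node {node!r} missing from catalog")
        self.total_pairs_used = total_pairs_used
        self.normalized = normalized

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterator[ContactEdge]:
        for u, v, data in self.graph.edges(data=True):
            a, b = (u, v) if u < v else (v, u)
            yield ContactEdge(a, b, data["raw_count"], data["weight"])

    def edge(self, a: str, b: str) -> ContactEdge:
        data = self.graph.edges[a, b]
        a, b = (a, b) if a < b else (b, a)
        return ContactEdge(a, b, data["raw_count"], data["weight"])

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def subnetwork(self, contig_ids: Iterable[str]) -> "ContactNetwork":
        """Restriction to a contig subset (used by the recursive procedure)."""
        wanted = set(contig_ids)
        sub = self.graph.subgraph(wanted).copy()
        return ContactNetwork(
            self.catalog.subset(wanted),
            sub,
            total_pairs_used=int(sum(d["raw_count"] for _, _, d in sub.edges(data=True))),
            normalized=self.normalized,
        )


def filter_contigs(catalog: ContigCatalog, min_length: int = DEFAULT_MIN_CONTIG_LENGTH) -> ContigCatalog:
    """Discard contigs shorter than ``min_length`` bp (default 500).

    Contigs of exactly ``min_length`` are retained: only strictly shorter
    contigs are removed.
    """
    return catalog.filter_by_length(min_length)


def _mate_passes(rec: AlignedRead, mapq_threshold: int) -> bool:
    return not rec.ambiguous and rec.mapq >= mapq_threshold


def pair_reads(
    alignments: Iterable[AlignedRead],
    mapq_threshold: int = DEFAULT_MIN_MAPQ,
    dedup: bool = False,
) -> Tuple[List[Tuple[str, str]], PairingStats]:
    """Match mates by read id and emit inter-contig pairs.

    A pair is emitted iff *both* mates are unambiguous, have mapping
    quality >= ``mapq_threshold`` (mapq equal to the threshold passes) and
    map to two different contigs. Everything else is dropped and counted
    by category: same-contig pairs, low-mapq, ambiguous (including reads
    with more than two records), and unmatched singleton mates. With
    ``dedup`` a pair whose two alignment coordinates (contig, position)
    were already seen is dropped as a PCR duplicate (input is normally
    deduplicated upstream, e.g. via ligation tags).

    Returns the list of unordered ``(contig_a, contig_b)`` pairs (in
    canonical sorted order) and a :class:`PairingStats`.
    """
    by_read: Dict[str, Dict[int, List[AlignedRead]]] = defaultdict(lambda: defaultdict(list))
    for rec in alignments:
        by_read[rec.read_id][rec.mate].append(rec)

    stats = PairingStats()
    pairs: List[Tuple[str, str]] = []
    seen_ids: set = set()
    for read_id, mates in by_read.items():
        recs = [r for lst in mates.values() for r in lst]
        if len(recs) > 2 or any(len(lst) > 1 for lst in mates.values()):
            # a mate with several records is a multi-mapper
            stats.ambiguous += 1
            continue
        if len(mates) < 2:
            stats.unmatched_singleton += 1
            continue
        (m1,) = mates[1]
        (m2,) = mates[2]
        if m1.ambiguous or m2.ambiguous:
            stats.ambiguous += 1
            continue
        if m1.mapq < mapq_threshold or m2.mapq < mapq_threshold:
            stats.low_mapq += 1
            continue
        if m1.contig_id == m2.contig_id:
            stats.same_contig += 1
            continue
        if dedup:
            sig = tuple(sorted(((m1.contig_id, m1.position), (m2.contig_id, m2.position))))
            if sig in seen_ids:
                stats.duplicate += 1
                continue
            seen_ids.add(sig)
        a, b = sorted((m1.contig_id, m2.contig_id))
        pairs.append((a, b))
        stats.emitted += 1
    return pairs, stats


def build_network(
    pairs: Iterable[Tuple[str, str]],
    catalog: ContigCatalog,
) -> ContactNetwork:
    """Tally unordered contig pairs into a raw-count contact network.

    Pairs touching a contig absent from the (filtered) catalog are dropped
    with a warning and counted; self-pairs never arise from
    :func:`pair_reads` but are rejected defensively.
    """
    counts: Counter = Counter()
    dropped_unknown = 0
    used = 0
    for a, b in pairs:
        if a == b:
            raise ValueError(f"self-pair ({a!r}, {a!r}) reached build_network")
        if a not in catalog or b not in catalog:
            dropped_unknown += 1
            continue
        if a > b:
            a, b = b, a
        counts[(a, b)] += 1
        used += 1
    if dropped_unknown:
        warnings.warn(
            f"{dropped_unknown} pairs touched contigs absent from the catalog and were dropped",
            stacklevel=2,
        )
    g = nx.Graph()
    g.add_nodes_from(catalog.ids)
    for (a, b), n in counts.items():
        g.add_edge(a, b, raw_count=n, weight=float(n))
    net = ContactNetwork(catalog, g, total_pairs_used=used, normalized=False)
    net.dropped_unknown = dropped_unknown
    return net


def normalize_network(net: ContactNetwork) -> ContactNetwork:
    """Divide each raw count by the geometric mean of endpoint coverages.

    weight(a, b) = raw_count(a, b) / sqrt(coverage(a) * coverage(b)).
    Raw counts are preserved alongside. Edges with a zero-coverage
    endpoint are undefined under this formula and dropped with a warning
    (no pseudo-count is substituted, to keep weights interpretable).
    """
    g = nx.Graph()
    g.add_nodes_from(net.catalog.ids)
    dropped_zero_cov = 0
    for u, v, data in net.graph.edges(data=True):
        ca = net.catalog.coverage_of(u)
        cb = net.catalog.coverage_of(v)
        if ca <= 0 or cb <= 0:
            dropped_zero_cov += 1
            continue
        w = data["raw_count"] / math.sqrt(ca * cb)
        g.add_edge(u, v, raw_count=data["raw_count"], weight=w)
    if dropped_zero_cov:
        warnings.warn(
            f"{dropped_zero_cov} edges dropped: zero-coverage endpoint makes the "
            "normalized weight undefined",
            stacklevel=2,
        )
    out = ContactNetwork(net.catalog, g, total_pairs_used=net.total_pairs_used, normalized=True)
    out.dropped_zero_coverage = dropped_zero_cov
    return out


def compute_coverage(
    alignments: Iterable[AlignedRead],
    catalog: ContigCatalog,
    mapq_threshold: int = DEFAULT_MIN_MAPQ,
) -> ContigCatalog:
    """Mean read depth per contig from filtered alignments.

    coverage(c) = (total aligned bases on c) / length(c), applying the
    same ambiguity/mapq filter as pairing. Intra-contig (cis) pairs do
    contribute — they are aligned bases. Contigs without alignments get
    coverage 0. Returns a new catalog.
    """
    bases: Dict[str, int] = defaultdict(int)
    for rec in alignments:
        if not _mate_passes(rec, mapq_threshold):
            continue
        if rec.contig_id in catalog:
            bases[rec.contig_id] += rec.read_length
    return catalog.with_coverage(
        {cid: n / catalog.length_of(cid) for cid, n in bases.items()}
    )


def read_sam_alignments(path: str) -> Iterator[AlignedRead]:
    """Stream :class:`AlignedRead` records from a SAM/BAM of single-end mates.

    Mate number is taken from the paired-end FLAG bits when present, else
    from a trailing ``/1`` / ``/2`` on the read name. Secondary and
    supplementary records are flagged ambiguous.
    """
    import pysam

    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            name = rec.query_name
            if rec.is_paired:
                mate = 1 if rec.is_read1 else 2
            elif name.endswith(("/1", "/2")):
                mate = int(name[-1])
                name = name[:-2]
            else:
                mate = 1
            yield AlignedRead(
                read_id=name,
                mate=mate,
                contig_id=rec.reference_name,
                position=rec.reference_start,
                mapq=rec.mapping_quality,
                ambiguous=rec.is_secondary or rec.is_supplementary,
                read_length=rec.query_alignment_length or (rec.query_length or 0),
            )
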