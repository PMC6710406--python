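"""Ground-truthed synthetic proximity-ligation communities.

The generator emulates the one physical fact the binning method rests
on: loci packaged in the same cell contact each other far more often
than loci in different cells. Each genome is a set of contigs with a
shared abundance; read-pair counts between two contigs are Poisson with
a rate proportional to the product of contig lengths and the geometric
mean of their coverages — large or deeply sequenced contigs simply
collect more ligation events — times a contact propensity that is high
(``intra_rate``) when the contigs share a host genome and low
(``inter_rate``) otherwise. Because the rate carries exactly the
sqrt(cov_a * cov_b) factor that coverage normalization divides out,
normalized intra-genome weights are approximately flat and the planted
structure is analytically predictable.

Mobile elements are modeled as contigs hosted by several genomes
(``shared_contig_frac``, ``bridge_groups``): they contact all their
hosts at the intra rate, which is what lets them bridge otherwise
separate genomes into one contaminated core community.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from proxibin.catalog import Contig, ContigCatalog
from proxibin.network import AlignedRead
from proxibin.quality import MarkerTable

#: the 20 canonical amino-acid tRNA isotypes
TRNA_TYPES = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)


@dataclass
class CommunitySpec:
    """Parameters of one synthetic community.

    ``intra_rate`` is the expected number of read pairs between two
    same-genome contigs of reference length and coverage; ``inter_rate``
    plays the same role across genomes, so their ratio is the
    signal-to-noise of the planted structure (default 5.0 / 0.02 = 250).
    ``mean_contig_length`` and ``mean_coverage`` set the reference scales
    the rates are quoted at. ``abundance_sigma`` is the lognormal spread
    of genome abundances (which sum to 1); ``coverage_noise_sigma`` adds
    per-contig multiplicative depth noise. ``shared_contig_frac`` places
    a fraction of contigs into a second random genome; ``bridge_groups``
    plants explicit conserved contigs shared by whole genome groups
    (``n_bridge_contigs`` each). ``noise_frac`` corrupts that fraction of
    read pairs with a low-mapq or ambiguous mate so alignment filters
    have something to remove.
    """

    n_genomes: int = 10
    contigs_per_genome: int = 50
    mean_contig_length: int = 20_000
    length_sigma: float = 0.6
    min_contig_length: int = 100
    mean_coverage: float = 10.0
    abundance_sigma: float = 0.5
    coverage_noise_sigma: float = 0.2
    intra_rate: float = 5.0
    inter_rate: float = 0.02
    shared_contig_frac: float = 0.0
    bridge_groups: Tuple[Tuple[int, ...], ...] = ()
    n_bridge_contigs: int = 4
    noise_frac: float = 0.0
    marker_set_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("a community needs at least one genome")
        if self.intra_rate < 0 or self.inter_rate < 0:
            raise ValueError("contact rates must be >= 0")
        if self.intra_rate <= self.inter_rate and self.intra_rate > 0:
            raise ValueError("intra_rate must exceed inter_rate for any signal to exist")
        if not 0 <= self.shared_contig_frac <= 1:
            raise ValueError("shared_contig_frac must be in [0, 1]")
        if not 0 <= self.noise_frac <= 1:
            raise ValueError("noise_frac must be in [0, 1]")


@dataclass
class GroundTruth:
    """Who owns what in a simulated community.

    ``hosts`` maps every contig id to the tuple of genomes carrying it
    (shared contigs carry several); per-genome marker complements and
    tRNA/rRNA content close the loop with the quality module.
    """

    genomes: List[str]
    hosts: Dict[str, Tuple[str, ...]]
    markers_per_genome: Dict[str, List[str]] = field(default_factory=dict)
    trna_types: Dict[str, Tuple[str, ...]] = field(default_factory=dict)
    rrnas: Dict[str, Tuple[bool, bool, bool]] = field(default_factory=dict)

    def members(self, genome: str) -> set:
        return {cid for cid, hs in self.hosts.items() if genome in hs}

    def exclusive_members(self, genome: str) -> set:
        return {cid for cid, hs in self.hosts.items() if hs == (genome,)}

    def shared_contigs(self) -> set:
        return {cid for cid, hs in self.hosts.items() if len(hs) > 1}

    def primary_host(self, contig_id: str) -> str:
        return self.hosts[contig_id][0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig_id": list(self.hosts),
                "genomes": [",".join(hs) for hs in self.hosts.values()],
            }
        )


def simulate_community(spec: CommunitySpec) -> Tuple[ContigCatalog, GroundTruth]:
    """Draw genomes, contigs, abundances and coverages.

    Contig lengths are lognormal around ``mean_contig_length`` (floored
    at ``min_contig_length``); genome abundances are lognormal and sum to
    1; coverage of a contig is the summed depth of its host genomes
    (depth = abundance * n_genomes * mean_coverage) with multiplicative
    lognormal noise. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    genomes = [f"genome_{g:02d}" for g in range(spec.n_genomes)]
    abund = rng.lognormal(mean=0.0, sigma=spec.abundance_sigma, size=spec.n_genomes)
    abund = abund / abund.sum()
    depth = {g: abund[i] * spec.n_genomes * spec.mean_coverage for i, g in enumerate(genomes)}

    hosts: Dict[str, Tuple[str, ...]] = {}
    lengths: Dict[str, int] = {}
    mu = np.log(spec.mean_contig_length) - spec.length_sigma**2 / 2
    for gi, g in enumerate(genomes):
        for k in range(spec.contigs_per_genome):
            cid = f"g{gi:02d}_c{k:03d}"
            lengths[cid] = max(spec.min_contig_length, int(rng.lognormal(mu, spec.length_sigma)))
            hosts[cid] = (g,)

    # mobile contigs: a second random host genome
    if spec.shared_contig_frac > 0 and spec.n_genomes > 1:
        ids = list(hosts)
        n_shared = int(round(spec.shared_contig_frac * len(ids)))
        for cid in rng.choice(ids, size=n_shared, replace=False):
            current = hosts[cid][0]
            others = [g for g in genomes if g != current]
            extra = others[rng.integers(len(others))]
            hosts[cid] = (current, extra)

    # planted conserved-sequence bridges across whole genome groups
    for bi, group in enumerate(spec.bridge_groups):
        names = tuple(genomes[i] for i in group)
        for k in range(spec.n_bridge_contigs):
            cid = f"bridge{bi:02d}_c{k:02d}"
            lengths[cid] = max(spec.min_contig_length, int(rng.lognormal(mu, spec.length_sigma)))
            hosts[cid] = names

    contigs = []
    for cid, hs in hosts.items():
        base = sum(depth[g] for g in hs)
        cov = base * rng.lognormal(0.0, spec.coverage_noise_sigma)
        contigs.append(Contig(id=cid, length=lengths[cid], coverage=float(cov)))
    truth = GroundTruth(
        genomes=genomes,
        hosts=hosts,
        markers_per_genome={g: [f"m{j:03d}" for j in range(spec.marker_set_size)] for g in genomes},
        trna_types={g: TRNA_TYPES for g in genomes},
        rrnas={g: (True, True, True) for g in genomes},
    )
    return ContigCatalog(contigs), truth


def _pair_rate(spec: CommunitySpec, la: int, lb: int, ca: float, cb: float, same: bool) -> float:
    r = spec.intra_rate if same else spec.inter_rate
    scale = (la / spec.mean_contig_length) * (lb / spec.mean_contig_length)
    return r * scale * np.sqrt(ca * cb) / spec.mean_coverage


def expected_pair_count(
    spec: CommunitySpec, len_a: int, len_b: int, cov_a: float, cov_b: float, same_genome: bool
) -> float:
    """Analytic Poisson mean for one contig pair (exposed for tests)."""
    return float(_pair_rate(spec, len_a, len_b, cov_a, cov_b, same_genome))


def simulate_pairs(
    catalog: ContigCatalog,
    truth: GroundTruth,
    spec: CommunitySpec,
    as_reads: bool = False,
):
    """Draw the Poisson contact counts for every contig pair.

    Returns a list of unordered contig-id pairs, or with ``as_reads`` a
    list of :class:`AlignedRead` records (two single-end mates per pair,
    65 bp, mapq 42) of which a ``noise_frac`` fraction of pairs has one
    mate corrupted to mapq < 20 or flagged ambiguous. Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    ids = catalog.ids
    n = len(ids)
    lens = np.array([catalog.length_of(c) for c in ids], dtype=float)
    covs = np.array([catalog.coverage_of(c) for c in ids], dtype=float)
    host_sets = [set(truth.hosts[c]) for c in ids]

    pairs: List[Tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            same = bool(host_sets[i] & host_sets[j])
            rate = _pair_rate(spec, lens[i], lens[j], covs[i], covs[j], same)
            if rate <= 0:
                continue
            k = rng.poisson(rate)
            if k:
                a, b = sorted((ids[i], ids[j]))
                pairs.extend([(a, b)] * int(k))
    if not as_reads:
        return pairs

    reads: List[AlignedRead] = []
    for idx, (a, b) in enumerate(pairs):
        rid = f"r{idx:08d}"
        mapq = [42, 42]
        ambiguous = [False, False]
        if spec.noise_frac > 0 and rng.random() < spec.noise_frac:
            which = int(rng.integers(2))
            if rng.random() < 0.5:
                mapq[which] = int(rng.integers(0, 20))
            else:
                ambiguous[which] = True
        for m, (cid, q, amb) in enumerate(zip((a, b), mapq, ambiguous), start=1):
            pos = int(rng.integers(0, max(1, catalog.length_of(cid) - 65)))
            reads.append(
                AlignedRead(
                    read_id=rid, mate=m, contig_id=cid, position=pos,
                    mapq=q, ambiguous=amb, read_length=65,
                )
            )
    return reads


def simulate_annotations(
    truth: GroundTruth,
    marker_set_size: Optional[int] = None,
    seed: int = 0,
) -> Tuple[MarkerTable, pd.DataFrame]:
    """Scatter each genome's marker complement and RNA genes onto its contigs.

    Every genome carries one copy of each universal single-copy marker,
    placed on a uniformly random member contig (shared contigs may
    therefore accumulate markers of several genomes — exactly how real
    conserved sequences inflate contamination). tRNA types and the three
    rRNA genes are placed the same way. Returns the marker table and a
    per-contig feature frame with columns ``contig_id`` / ``feature``
    consumed by :func:`proxibin.quality.aggregate_rna`.
    """
    rng = np.random.default_rng(seed)
    hits: Dict[Tuple[str, str], int] = {}
    feature_rows: List[Tuple[str, str]] = []
    all_markers: set = set()
    for g in truth.genomes:
        members = sorted(truth.members(g))
        markers = truth.markers_per_genome.get(g, [])
        all_markers.update(markers)
        for mid in markers:
            cid = members[rng.integers(len(members))]
            hits[(cid, mid)] = hits.get((cid, mid), 0) + 1
        for t in truth.trna_types.get(g, ()):
            cid = members[rng.integers(len(members))]
            feature_rows.append((cid, f"tRNA-{t}"))
        has_5s, has_16s, has_23s = truth.rrnas.get(g, (False, False, False))
        for flag, name in ((has_5s, "rRNA_5S"), (has_16s, "rRNA_16S"), (has_23s, "rRNA_23S")):
            if flag:
                cid = members[rng.integers(len(members))]
                feature_rows.append((cid, name))
    table = MarkerTable(all_markers, hits)
    features = pd.DataFrame(feature_rows, columns=["contig_id", "feature"])
    return table, features


def random_sequences(catalog: ContigCatalog, seed: int = 0) -> Dict[str, str]:
    """Uniform-random ACGT sequences of the catalog's stated lengths."""
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    return {
        c.id: rng.choice(alphabet, size=c.length).tobytes().decode()
        for c in catalog
    }
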