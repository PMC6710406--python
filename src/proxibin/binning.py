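"""Bin validation and recursive deconvolution of contaminated CCs.

Core communities above 500 kb are scored for completeness and
contamination. A CC is a valid bin when its contamination is under 10%.
CCs that are largely complete (>70%) yet contaminated (>10%) usually
pool several related genomes bridged by conserved sequences; those are
re-partitioned on their own sub-network with a short Louvain iteration
(10 runs), and the resulting sub-CCs replace the parent in the final bin
set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

from proxibin.partition import CoreCommunity, core_communities, iterate_louvain

DEFAULT_CC_MIN_BP = 500_000


@dataclass
class BinCandidate:
    """A CC or sub-CC under evaluation as a genome bin.

    ``bin_id`` is the CC id, or ``"<cc_id>.<k>"`` for a sub-CC from the
    recursive procedure; ``origin`` records which stage produced it.
    Completeness/contamination are percentages (contamination may exceed
    100% when a bin pools several marker complements) and stay ``None``
    until the quality module scores the bin.
    """

    bin_id: str
    contig_ids: frozenset
    total_bp: int
    completeness: Optional[float] = None
    contamination: Optional[float] = None
    origin: str = "primary"
    sub_network: Optional[object] = None
    tier: Optional[str] = None

    @classmethod
    def from_cc(cls, cc: CoreCommunity, origin: str = "primary") -> "BinCandidate":
        return cls(
            bin_id=str(cc.cc_id),
            contig_ids=cc.contig_ids,
            total_bp=cc.total_bp,
            origin=origin,
            sub_network=cc.sub_network,
        )


@dataclass
class RecursionConfig:
    """Thresholds and run count for the recursive procedure.

    A CC enters recursion when completeness > ``completeness_min`` (70%)
    AND contamination > ``contamination_min`` (10%), both strict. The
    sub-network is then re-partitioned with ``n_recursive_runs`` (10)
    Louvain runs, all of which are pooled for the sub-CC meet.
    """

    completeness_min: float = 70.0
    contamination_min: float = 10.0
    n_recursive_runs: int = 10
    max_depth: int = 1

    def __post_init__(self) -> None:
        if min(self.completeness_min, self.contamination_min) < 0:
            raise ValueError("thresholds must be >= 0")
        if self.n_recursive_runs < 1:
            raise ValueError("n_recursive_runs must be >= 1")


def select_evaluable(
    ccs: Sequence[CoreCommunity], min_bp: int = DEFAULT_CC_MIN_BP
) -> List[CoreCommunity]:
    """CCs strictly above ``min_bp`` total bp (default 500 kb), order kept."""
    if min_bp < 0:
        raise ValueError("min_bp must be >= 0")
    return [cc for cc in ccs if cc.total_bp > min_bp]


def validate_bin(candidate: BinCandidate, contamination_max: float = 10.0) -> bool:
    """True iff the candidate's contamination is strictly under the cap."""
    if candidate.contamination is None:
        raise ValueError(f"bin {candidate.bin_id}: contamination not computed")
    return candidate.contamination < contamination_max


def select_for_recursion(
    candidates: Sequence[BinCandidate], cfg: RecursionConfig = RecursionConfig()
) -> List[BinCandidate]:
    """Candidates with completeness > 70% and contamination > 10% (strict)."""
    out = []
    for c in candidates:
        if c.completeness is None or c.contamination is None:
            raise ValueError(f"bin {c.bin_id}: quality metrics not computed")
        if c.completeness > cfg.completeness_min and c.contamination > cfg.contamination_min:
            out.append(c)
    return out


def recursive_partition(
    cc: CoreCommunity,
    cfg: RecursionConfig = RecursionConfig(),
    seed: int = 0,
) -> List[BinCandidate]:
    """Re-partition one contaminated CC on its own sub-network.

    Runs ``cfg.n_recursive_runs`` Louvain iterations on the sub-network
    only and pools all of them into sub-CCs (the same meet rule as the
    primary stage, at smaller n). Returns the sub-CCs as bin candidates
    with ids ``"<cc_id>.<k>"``; their members exactly partition the
    parent's members. A sub-network without edges degenerates to
    singleton sub-CCs (with a warning).
    """
    if cc.sub_network is None:
        raise ValueError(f"CC {cc.cc_id} carries no sub-network; recursion needs one")
    sub = cc.sub_network
    if sub.n_edges == 0:
        warnings.warn(
            f"CC {cc.cc_id}: sub-network has no edges; recursion yields singleton sub-CCs",
            stacklevel=2,
        )
    parts = iterate_louvain(sub, cfg.n_recursive_runs, base_seed=seed)
    sub_ccs = core_communities(parts, cfg.n_recursive_runs, sub.catalog, network=sub)
    out = [
        BinCandidate(
            bin_id=f"{cc.cc_id}.{scc.cc_id}",
            contig_ids=scc.contig_ids,
            total_bp=scc.total_bp,
            origin="recursive",
            sub_network=scc.sub_network,
        )
        for scc in sub_ccs
    ]
    covered = frozenset().union(*(b.contig_ids for b in out))
    assert covered == cc.contig_ids, "sub-CCs must partition the parent CC"
    return out


def finalize_bins(
    primary: Sequence[BinCandidate], recursive: Sequence[BinCandidate]
) -> List[BinCandidate]:
    """Assemble the final bin set: untouched primary CCs plus all sub-CCs.

    Callers must have removed the recursed parents from ``primary``; any
    contig appearing in two final bins violates the partition invariant
    and raises.
    """
    out = list(primary) + list(recursive)
    seen: Dict[str, str] = {}
    for b in out:
        for cid in b.contig_ids:
            if cid in seen:
                raise ValueError(
                    f"contig {cid!r} appears in bins {seen[cid]!r} and {b.bin_id!r}"
                )
            seen[cid] = b.bin_id
    return out
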