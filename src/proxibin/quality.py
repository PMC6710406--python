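"""Bin quality: marker-based completeness/contamination and MIMAG tiers.

The scoring model is the classic single-copy-marker argument: a complete,
uncontaminated genome carries each universal single-copy marker exactly
once. Completeness is the fraction of the marker set present at least
once in a bin; contamination is the excess copy count relative to the set
size. This deliberately simplifies lineage-aware tools like CheckM (no
lineage-specific sets, no collocated-set correction) — a reader for
CheckM's tabular output lets users substitute real scores while keeping
the downstream tier logic identical.

MIMAG tiers: high needs <5% contamination, >90% completeness, >=18
distinct tRNAs and all three rRNA genes (5S, 16S, 23S); medium needs
<10% contamination and >=50% completeness; low needs <10% contamination
and <50% completeness; anything at >=10% contamination is `contaminated`.
The tRNA/rRNA criteria apply to the high tier only.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from proxibin.binning import BinCandidate

SIZE_CLASSES = (
    ("10-100 kb", 10_000, 100_000),
    ("100-500 kb", 100_000, 500_000),
    (">500 kb", 500_000, None),
)

TIERS = ("high", "medium", "low", "contaminated", "unevaluated")


class MarkerTable:
    """Copy counts of single-copy markers per contig.

    ``hits`` maps ``(contig_id, marker_id) -> copies`` (>= 1); ``markers``
    is the full marker universe the completeness denominator uses, which
    may include markers never observed on any contig.
    """

    def __init__(
        self,
        markers: Iterable[str],
        hits: Mapping[Tuple[str, str], int],
        marker_set_id: str = "universal",
    ):
        self.marker_set_id = marker_set_id
        self.markers = sorted(set(markers))
        if not self.markers:
            raise ValueError("marker set must be non-empty")
        self.hits: Dict[Tuple[str, str], int] = {}
        for (cid, mid), n in hits.items():
            if n < 1:
                raise ValueError(f"copy count must be >= 1, got {n} for {(cid, mid)}")
            if mid not in set(self.markers):
                raise ValueError(f"hit references unknown marker {mid!r}")
            self.hits[(cid, mid)] = int(n)
        self._by_contig: Dict[str, Dict[str, int]] = defaultdict(dict)
        for (cid, mid), n in self.hits.items():
            self._by_contig[cid][mid] = n

    def contig_hits(self, contig_id: str) -> Dict[str, int]:
        return dict(self._by_contig.get(contig_id, {}))

    def to_frame(self) -> pd.DataFrame:
        rows = [(cid, mid, n) for (cid, mid), n in sorted(self.hits.items())]
        return pd.DataFrame(rows, columns=["contig_id", "marker_id", "copies"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, markers: Optional[Iterable[str]] = None) -> "MarkerTable":
        hits = {
            (str(r.contig_id), str(r.marker_id)): int(r.copies)
            for r in df.itertuples(index=False)
        }
        if markers is None:
            markers = {m for (_, m) in hits}
        return cls(markers, hits)


@dataclass(frozen=True)
class RnaProfile:
    """Distinct-tRNA count and rRNA-gene presence flags for one bin."""

    n_distinct_trnas: int = 0
    has_5s: bool = False
    has_16s: bool = False
    has_23s: bool = False

    def __post_init__(self) -> None:
        if self.n_distinct_trnas < 0:
            raise ValueError("n_distinct_trnas must be >= 0")

    @property
    def all_rrnas(self) -> bool:
        return self.has_5s and self.has_16s and self.has_23s


def score_bin(bin: BinCandidate, markers: MarkerTable) -> Tuple[float, float]:
    """Completeness and contamination of a bin, both in percent.

    completeness = 100 * |markers with >= 1 copy in the bin| / |marker set|
    contamination = 100 * sum_m max(0, copies_m - 1) / |marker set|

    Contamination is unbounded above: a bin pooling k whole single-copy
    complements scores 100% complete and 100*(k-1)% contaminated.
    """
    n_set = len(markers.markers)
    copies: Dict[str, int] = defaultdict(int)
    for cid in bin.contig_ids:
        for mid, n in markers.contig_hits(cid).items():
            copies[mid] += n
    present = sum(1 for n in copies.values() if n >= 1)
    excess = sum(n - 1 for n in copies.values() if n > 1)
    return 100.0 * present / n_set, 100.0 * excess / n_set


def classify_mimag(
    completeness: float, contamination: float, rna: Optional[RnaProfile] = None
) -> str:
    """Assign the MIMAG quality tier for one evaluated bin.

    Boundaries are as printed in the standard: high requires strictly
    >90% completeness and <5% contamination plus the RNA criteria; medium
    requires >=50% completeness; the contamination cap of 10% is strict
    throughout; >=10% contamination is `contaminated`.
    """
    if rna is None:
        rna = RnaProfile()
    if (
        contamination < 5.0
        and completeness > 90.0
        and rna.n_distinct_trnas >= 18
        and rna.all_rrnas
    ):
        return "high"
    if contamination < 10.0 and completeness >= 50.0:
        return "medium"
    if contamination < 10.0 and completeness < 50.0:
        return "low"
    return "contaminated"


def aggregate_rna(contig_ids: Iterable[str], features: pd.DataFrame) -> RnaProfile:
    """Pool per-contig RNA annotations into one bin-level profile.

    ``features`` has columns ``contig_id`` and ``feature``; tRNA features
    are ``tRNA-<type>`` (distinct types counted once per bin) and rRNA
    features are ``rRNA_5S`` / ``rRNA_16S`` / ``rRNA_23S``.
    """
    members = set(contig_ids)
    sub = features[features["contig_id"].isin(members)]
    feats = set(sub["feature"])
    trnas = {f for f in feats if f.startswith("tRNA-")}
    return RnaProfile(
        n_distinct_trnas=len(trnas),
        has_5s="rRNA_5S" in feats,
        has_16s="rRNA_16S" in feats,
        has_23s="rRNA_23S" in feats,
    )


def _size_class(total_bp: int) -> Optional[str]:
    for name, lo, hi in SIZE_CLASSES:
        if total_bp >= lo and (hi is None or total_bp < hi):
            return name
    return None


def summarize_run(bins: Sequence[BinCandidate]) -> pd.DataFrame:
    """Counts and cumulative bp per size class and quality tier.

    Rows are (tier, size_class) with columns ``n_bins`` and ``total_bp``;
    every tier/size-class combination is present (zero-filled), so an
    empty bin list yields an all-zero report. Bins under 10 kb are
    excluded from the size classes, mirroring the usual report layout.
    """
    rows = []
    for tier in TIERS:
        for name, _, _ in SIZE_CLASSES:
            members = [
                b
                for b in bins
                if (b.tier or "unevaluated") == tier and _size_class(b.total_bp) == name
            ]
            rows.append(
                {
                    "tier": tier,
                    "size_class": name,
                    "n_bins": len(members),
                    "total_bp": sum(b.total_bp for b in members),
                }
            )
    return pd.DataFrame(rows)


def read_checkm_table(path: str) -> pd.DataFrame:
    """Read a CheckM-style tab-separated quality table.

    Expects at least the columns ``Bin Id``, ``Completeness`` and
    ``Contamination`` (CheckM's ``qa`` tabular output); returns a frame
    with columns ``bin_id``, ``completeness``, ``contamination`` so real
    scores can replace the internal marker model downstream.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"Bin Id", "Completeness", "Contamination"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CheckM table missing columns: {sorted(missing)}")
    return pd.DataFrame(
        {
            "bin_id": df["Bin Id"].astype(str),
            "completeness": df["Completeness"].astype(float),
            "contamination": df["Contamination"].astype(float),
        }
    )
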