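"""Contig catalog: the node universe of the contact network.

A :class:`ContigCatalog` is an ordered, id-unique collection of
:class:`Contig` records carrying length (bp), mean read-depth coverage and
an optional handle into a FASTA store. Catalogs are immutable; filtering
and coverage assignment return new catalogs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, Iterable, Iterator, Mapping, Optional

import pandas as pd


@dataclass(frozen=True)
class Contig:
    """One assembly contig.

    Parameters
    ----------
    id : str
        Unique, non-empty identifier.
    length : int
        Contig length in bp, >= 1.
    coverage : float
        Mean read depth (aligned bases / length), >= 0.
    sequence_ref : str, optional
        Handle into a FASTA store (usually the FASTA record id).
    """

    id: str
    length: int
    coverage: float = 0.0
    sequence_ref: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if self.length < 1:
            raise ValueError(f"contig {self.id!r}: length must be >= 1, got {self.length}")
        if self.coverage < 0:
            raise ValueError(f"contig {self.id!r}: coverage must be >= 0, got {self.coverage}")


class ContigCatalog:
    """Ordered, id-unique collection of contigs."""

    def __init__(self, contigs: Iterable[Contig] = ()):
        self._contigs: Dict[str, Contig] = {}
        for c in contigs:
            if c.id in self._contigs:
                raise ValueError(f"duplicate contig id {c.id!r}")
            self._contigs[c.id] = c

    def __len__(self) -> int:
        return len(self._contigs)

    def __iter__(self) -> Iterator[Contig]:
        return iter(self._contigs.values())

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._contigs

    def __getitem__(self, contig_id: str) -> Contig:
        return self._contigs[contig_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContigCatalog):
            return NotImplemented
        return self._contigs == other._contigs

    @property
    def ids(self) -> list:
        return list(self._contigs)

    @property
    def total_bp(self) -> int:
        return sum(c.length for c in self)

    def length_of(self, contig_id: str) -> int:
        return self._contigs[contig_id].length

    def coverage_of(self, contig_id: str) -> float:
        return self._contigs[contig_id].coverage

    def filter_by_length(self, min_length: int) -> "ContigCatalog":
        """Return a new catalog keeping contigs with length >= ``min_length``.

        The boundary is inclusive: only contigs strictly shorter than the
        threshold are discarded.
        """
        if min_length < 0:
            raise ValueError("min_length must be >= 0")
        kept = ContigCatalog(c for c in self if c.length >= min_length)
        if len(kept) == 0 and len(self) > 0:
            warnings.warn("length filter removed every contig", stacklevel=2)
        return kept

    def with_coverage(self, coverage: Mapping[str, float], missing: float = 0.0) -> "ContigCatalog":
        """Return a new catalog with coverages replaced from a mapping."""
        return ContigCatalog(
            replace(c, coverage=float(coverage.get(c.id, missing))) for c in self
        )

    def subset(self, contig_ids: Iterable[str]) -> "ContigCatalog":
        """Return a new catalog restricted to the given ids (catalog order kept)."""
        wanted = set(contig_ids)
        missing = wanted - set(self._contigs)
        if missing:
            raise KeyError(f"unknown contig ids: {sorted(missing)[:5]}")
        return ContigCatalog(c for c in self if c.id in wanted)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig_id": [c.id for c in self],
                "length": [c.length for c in self],
                "coverage": [c.coverage for c in self],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ContigCatalog":
        cov = df["coverage"] if "coverage" in df.columns else [0.0] * len(df)
        return cls(
            Contig(id=str(i), length=int(l), coverage=float(c))
            for i, l, c in zip(df["contig_id"], df["length"], cov)
        )
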