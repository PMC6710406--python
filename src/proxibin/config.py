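"""Pipeline configuration with the method's published defaults."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Union


@dataclass
class PipelineConfig:
    """Every threshold and flag of the pipeline, with its default.

    Defaults: contigs under 500 bp discarded; mates under mapping quality
    20 discarded; 400 Louvain iterations of which the first 100 are
    pooled into core communities; CCs above 500 kb evaluated; recursion
    on CCs with >70% completeness and >10% contamination, re-partitioned
    with 10 Louvain runs at depth 1. All randomness derives from ``seed``.
    """

    min_contig_len: int = 500
    min_mapq: int = 20
    normalize: str = "coverage"  # "coverage" | "none"
    dedup: bool = False
    iterations: int = 400
    use_iterations: int = 100
    cc_min_bp: int = 500_000
    rec_completeness: float = 70.0
    rec_contamination: float = 10.0
    rec_iterations: int = 10
    max_depth: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.normalize not in ("coverage", "none"):
            raise ValueError(f"unknown normalize mode {self.normalize!r}")
        if self.use_iterations > self.iterations:
            raise ValueError("use_iterations cannot exceed iterations")

    def to_file(self, path: Union[str, Path]) -> None:
        """Serialize to a flat key=value file (one entry per line)."""
        lines = []
        for f in fields(self):
            lines.append(f"{f.name}={getattr(self, f.name)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PipelineConfig":
        """Parse a key=value file written by :meth:`to_file`."""
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str, "bool": lambda s: s == "True"}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = casts[types[key]](value.strip())
        return cls(**kwargs)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
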