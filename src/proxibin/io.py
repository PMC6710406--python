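"""Readers and writers for the pipeline's plain-text formats.

The central artifact is ``network.txt``: three tab-separated columns —
node 1, node 2, weight — so that third-party tools can consume the
contact network directly. Raw counts and per-contig lengths/coverages
travel in sidecar TSVs. FASTA goes through Biopython.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from proxibin.catalog import Contig, ContigCatalog
from proxibin.network import AlignedRead, ContactNetwork

PathLike = Union[str, Path]


# ---------------------------------------------------------------- FASTA

def read_fasta(path: PathLike) -> Dict[str, str]:
    """FASTA file -> ordered dict of id -> sequence. Duplicate ids error."""
    store: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in store:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        store[rec.id] = str(rec.seq)
    if not store:
        warnings.warn(f"no FASTA records in {path}", stacklevel=2)
    return store


def write_fasta(path: PathLike, sequences: Dict[str, str]) -> None:
    """Write sequences as FASTA wrapped at 80 columns, ids verbatim."""
    records = [SeqRecord(Seq(s), id=cid, description="") for cid, s in sequences.items()]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=80).write_file(records)


def catalog_from_fasta(path: PathLike) -> ContigCatalog:
    """Build a catalog from FASTA record lengths (coverage 0)."""
    seqs = read_fasta(path)
    return ContigCatalog(
        Contig(id=cid, length=len(s), sequence_ref=cid) for cid, s in seqs.items()
    )


def write_bin_fastas(
    bins: Sequence, sequences: Dict[str, str], out_dir: PathLike
) -> List[Path]:
    """One ``<bin_id>.fa`` per bin, containing its member contigs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for b in bins:
        path = out_dir / f"{b.bin_id}.fa"
        write_fasta(path, {cid: sequences[cid] for cid in sorted(b.contig_ids)})
        written.append(path)
    return written


# -------------------------------------------------------------- network

def write_network(net: ContactNetwork, path: PathLike, sidecar: Optional[PathLike] = None) -> None:
    """Write ``network.txt`` (node1 TAB node2 TAB weight).

    Weights are serialized with ``repr`` so the reload is bit-stable. The
    optional sidecar TSV carries the raw pair counts per edge.
    """
    edges = sorted(net.edges(), key=lambda e: (e.contig_a, e.contig_b))
    with open(path, "w") as fh:
        for e in edges:
            fh.write(f"{e.contig_a}\t{e.contig_b}\t{e.weight!r}\n")
    if sidecar is not None:
        with open(sidecar, "w") as fh:
            fh.write("node1\tnode2\traw_count\n")
            for e in edges:
                fh.write(f"{e.contig_a}\t{e.contig_b}\t{e.raw_count}\n")


def read_network(
    path: PathLike,
    catalog: Optional[ContigCatalog] = None,
    sidecar: Optional[PathLike] = None,
) -> ContactNetwork:
    """Read a 3-column ``network.txt``.

    Pairs are canonicalized on read; a duplicate unordered pair or a
    malformed line is an error naming the line number. Without a catalog,
    unit-length zero-coverage contigs are fabricated for the node set (a
    nodes TSV via :func:`read_nodes` gives real lengths). Raw counts come
    from the sidecar when present, else default to 1.
    """
    raw: Dict[Tuple[str, str], int] = {}
    if sidecar is not None:
        side = pd.read_csv(sidecar, sep="\t")
        for r in side.itertuples(index=False):
            raw[tuple(sorted((str(r.node1), str(r.node2))))] = int(r.raw_count)

    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            a, b, w = parts
            try:
                weight = float(w)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: weight {w!r} is not a number") from None
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-edge {a!r}")
            if a > b:
                a, b = b, a
            if g.has_edge(a, b):
                raise ValueError(f"{path}:{lineno}: duplicate pair ({a!r}, {b!r})")
            g.add_edge(a, b, weight=weight, raw_count=raw.get((a, b), 1))
    if catalog is None:
        catalog = ContigCatalog(Contig(id=n, length=1) for n in sorted(g.nodes))
    return ContactNetwork(catalog, g, normalized=True)


def write_nodes(catalog: ContigCatalog, path: PathLike) -> None:
    """Per-contig sidecar: contig_id, length, coverage (bit-stable floats)."""
    catalog.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_nodes(path: PathLike) -> ContigCatalog:
    return ContigCatalog.from_frame(
        pd.read_csv(path, sep="\t", float_precision="round_trip")
    )


# ----------------------------------------------------------- read pairs

PAIRS_COLUMNS = ["readID", "contigA", "posA", "mapqA", "contigB", "posB", "mapqB"]


def write_pairs_tsv(reads: Sequence[AlignedRead], path: PathLike) -> int:
    """Write matched mate records as the pre-digested 7-column pairs TSV.

    The format carries no ambiguity flag: a pre-digested pair list only
    ever contains unambiguous alignments, so pairs with an ambiguous mate
    are excluded here (mapq filtering still happens downstream). Returns
    the number of pairs written.
    """
    by_read: Dict[str, Dict[int, AlignedRead]] = defaultdict(dict)
    for rec in reads:
        by_read[rec.read_id][rec.mate] = rec
    n = 0
    with open(path, "w") as fh:
        fh.write("\t".join(PAIRS_COLUMNS) + "\n")
        for rid, mates in by_read.items():
            if set(mates) != {1, 2}:
                continue  # singletons have no row in a pairs file
            a, b = mates[1], mates[2]
            if a.ambiguous or b.ambiguous:
                continue
            fh.write(
                f"{rid}\t{a.contig_id}\t{a.position}\t{a.mapq}"
                f"\t{b.contig_id}\t{b.position}\t{b.mapq}\n"
            )
            n += 1
    return n


def read_pairs_tsv(path: PathLike) -> List[AlignedRead]:
    """Read a 7-column pairs TSV back into per-mate alignment records."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PAIRS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pairs file {path} missing columns: {sorted(missing)}")
    reads: List[AlignedRead] = []
    for r in df.itertuples(index=False):
        reads.append(AlignedRead(str(r.readID), 1, str(r.contigA), int(r.posA), int(r.mapqA)))
        reads.append(AlignedRead(str(r.readID), 2, str(r.contigB), int(r.posB), int(r.mapqB)))
    return reads


# ---------------------------------------------------------------- tables

def write_bin_table(bins: Sequence, path: PathLike) -> None:
    """Final bin membership TSV: contig_id, bin_id, origin."""
    rows = []
    for b in bins:
        for cid in sorted(b.contig_ids):
            rows.append({"contig_id": cid, "bin_id": b.bin_id, "origin": b.origin})
    pd.DataFrame(rows, columns=["contig_id", "bin_id", "origin"]).to_csv(
        path, sep="\t", index=False
    )


def write_quality_table(bins: Sequence, rna_profiles: Dict[str, "object"], path: PathLike) -> None:
    """Per-bin quality TSV: scores, tier and RNA evidence."""
    rows = []
    for b in bins:
        rna = rna_profiles.get(b.bin_id)
        rows.append(
            {
                "bin_id": b.bin_id,
                "total_bp": b.total_bp,
                "completeness": "" if b.completeness is None else round(b.completeness, 4),
                "contamination": "" if b.contamination is None else round(b.contamination, 4),
                "tier": b.tier or "unevaluated",
                "n_tRNA": "" if rna is None else rna.n_distinct_trnas,
                "has_5S": "" if rna is None else rna.has_5s,
                "has_16S": "" if rna is None else rna.has_16s,
                "has_23S": "" if rna is None else rna.has_23s,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_partition_table(partitions: Sequence, path: PathLike) -> None:
    """Per-run label TSV: contig_id, run_id, label."""
    rows = []
    for p in partitions:
        for cid, lab in p.labels.items():
            rows.append((cid, p.run_id, lab))
    pd.DataFrame(rows, columns=["contig_id", "run_id", "label"]).to_csv(
        path, sep="\t", index=False
    )


def write_cc_table(ccs: Sequence, path: PathLike) -> None:
    """CC membership TSV: contig_id, cc_id."""
    rows = []
    for cc in ccs:
        for cid in sorted(cc.contig_ids):
            rows.append((cid, cc.cc_id))
    pd.DataFrame(rows, columns=["contig_id", "cc_id"]).to_csv(path, sep="\t", index=False)


def read_cc_table(path: PathLike) -> Dict[int, set]:
    df = pd.read_csv(path, sep="\t")
    out: Dict[int, set] = defaultdict(set)
    for r in df.itertuples(index=False):
        out[int(r.cc_id)].add(str(r.contig_id))
    return dict(out)


def write_scores_table(scores: Sequence, path: PathLike) -> None:
    """CC co-cluster score TSV: cc_a, cc_b, score."""
    rows = [(s.pair[0], s.pair[1], s.score) for s in scores]
    pd.DataFrame(rows, columns=["cc_a", "cc_b", "score"]).to_csv(path, sep="\t", index=False)
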