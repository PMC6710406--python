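"""End-to-end pipeline: align-derived pairs → network → CCs → bins → quality.

:func:`run_pipeline_objects` drives the whole method on in-memory
objects and is what the tests and the CLI both call;
:func:`run_pipeline` wraps it with file I/O, writes every intermediate
(network.txt, per-run labels, CC tables, bin membership, quality table,
summary) and a JSON manifest with config, seeds and per-stage record
counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from proxibin import io as pio
from proxibin.binning import (
    BinCandidate,
    RecursionConfig,
    finalize_bins,
    recursive_partition,
    select_evaluable,
    select_for_recursion,
)
from proxibin.catalog import ContigCatalog
from proxibin.config import PipelineConfig
from proxibin.network import (
    AlignedRead,
    ContactNetwork,
    PairingStats,
    build_network,
    filter_contigs,
    normalize_network,
    pair_reads,
)
from proxibin.partition import (
    CoreCommunity,
    Partition,
    core_communities,
    iterate_louvain,
)
from proxibin.quality import (
    MarkerTable,
    RnaProfile,
    aggregate_rna,
    classify_mimag,
    score_bin,
    summarize_run,
)

logger = logging.getLogger("proxibin")

#: offset added to the base seed for recursion, so primary and recursive
#: Louvain runs never share a seed stream (kept small: derived seeds must
#: stay below 2**31)
RECURSION_SEED_OFFSET = 100_000


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    """Everything the pipeline computed, stage by stage."""

    catalog: ContigCatalog
    network: ContactNetwork
    partitions: List[Partition]
    ccs: List[CoreCommunity]
    bins: List[BinCandidate]
    recursed_parents: List[BinCandidate]
    pairing_stats: PairingStats
    rna_profiles: Dict[str, RnaProfile]
    summary: pd.DataFrame
    manifest: Dict

    def bins_by_tier(self) -> Dict[str, List[BinCandidate]]:
        out: Dict[str, List[BinCandidate]] = {}
        for b in self.bins:
            out.setdefault(b.tier or "unevaluated", []).append(b)
        return out


def _cc_size_class_counts(ccs: Sequence[CoreCommunity]) -> Dict[str, int]:
    classes = {"10-100 kb": 0, "100-500 kb": 0, ">500 kb": 0}
    for cc in ccs:
        if 10_000 <= cc.total_bp < 100_000:
            classes["10-100 kb"] += 1
        elif 100_000 <= cc.total_bp < 500_000:
            classes["100-500 kb"] += 1
        elif cc.total_bp >= 500_000:
            classes[">500 kb"] += 1
    return classes


def _score_and_tier(
    candidate: BinCandidate,
    markers: Optional[MarkerTable],
    rna_features: Optional[pd.DataFrame],
) -> Optional[RnaProfile]:
    if markers is None:
        return None
    candidate.completeness, candidate.contamination = score_bin(candidate, markers)
    rna = (
        aggregate_rna(candidate.contig_ids, rna_features)
        if rna_features is not None
        else RnaProfile()
    )
    candidate.tier = classify_mimag(candidate.completeness, candidate.contamination, rna)
    return rna


def run_pipeline_objects(
    catalog: ContigCatalog,
    alignments: Union[Sequence[AlignedRead], Sequence[Tuple[str, str]]],
    config: PipelineConfig = PipelineConfig(),
    markers: Optional[MarkerTable] = None,
    rna_features: Optional[pd.DataFrame] = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs.

    ``alignments`` is either per-mate :class:`AlignedRead` records (the
    pairing filter is applied) or ready-made unordered contig-id pairs.
    Without a marker table the binning stage stops after CC extraction
    (no quality, no recursion). All randomness flows from ``config.seed``.
    """
    # [Align]: contig filter, mate pairing, network build + normalization
    catalog = filter_contigs(catalog, config.min_contig_len)
    if len(catalog) == 0:
        raise StageError("Align", "no contigs left after the length filter")
    if alignments and isinstance(alignments[0], AlignedRead):
        pairs, stats = pair_reads(alignments, config.min_mapq, dedup=config.dedup)
    else:
        pairs = list(alignments)
        stats = PairingStats(emitted=len(pairs))
    net = build_network(pairs, catalog)
    if config.normalize == "coverage":
        net = normalize_network(net)
    logger.info(
        "[Align] %d contigs, %d pairs used, %d edges",
        len(catalog), net.total_pairs_used, net.n_edges,
    )

    # [Partition]: iterated Louvain, core communities
    partitions = iterate_louvain(net, config.iterations, base_seed=config.seed)
    n_use = min(config.use_iterations, config.iterations)
    ccs = core_communities(partitions, n_use, catalog, network=net)
    logger.info("[Partition] %d runs, %d CCs from the first %d", len(partitions), len(ccs), n_use)

    # [Binning]: evaluate large CCs, recurse the contaminated ones
    evaluable_ids = {cc.cc_id for cc in select_evaluable(ccs, config.cc_min_bp)}
    candidates = [BinCandidate.from_cc(cc) for cc in ccs]
    rna_profiles: Dict[str, RnaProfile] = {}
    for cand, cc in zip(candidates, ccs):
        if cc.cc_id in evaluable_ids and markers is not None:
            rna = _score_and_tier(cand, markers, rna_features)
            if rna is not None:
                rna_profiles[cand.bin_id] = rna

    rec_cfg = RecursionConfig(
        completeness_min=config.rec_completeness,
        contamination_min=config.rec_contamination,
        n_recursive_runs=config.rec_iterations,
        max_depth=config.max_depth,
    )
    scored = [c for c in candidates if c.completeness is not None]
    to_recurse = select_for_recursion(scored, rec_cfg) if markers is not None else []
    recurse_ids = {c.bin_id for c in to_recurse}
    cc_by_id = {str(cc.cc_id): cc for cc in ccs}
    sub_bins: List[BinCandidate] = []
    for cand in to_recurse:
        parent = cc_by_id[cand.bin_id]
        subs = recursive_partition(
            parent, rec_cfg, seed=config.seed + RECURSION_SEED_OFFSET + parent.cc_id
        )
        for sb in subs:
            if markers is not None and sb.total_bp > config.cc_min_bp:
                rna = _score_and_tier(sb, markers, rna_features)
                if rna is not None:
                    rna_profiles[sb.bin_id] = rna
        sub_bins.extend(subs)
    primary_kept = [c for c in candidates if c.bin_id not in recurse_ids]
    bins = finalize_bins(primary_kept, sub_bins)
    logger.info(
        "[Binning] %d CCs evaluated, %d recursed into %d sub-CCs, %d final bins",
        len(evaluable_ids), len(to_recurse), len(sub_bins), len(bins),
    )

    # [Annotation]: summary report
    summary = summarize_run(bins)

    from proxibin import __version__

    manifest = {
        "proxibin_version": __version__,
        "config": config.as_dict(),
        "seed": config.seed,
        "n_contigs": len(catalog),
        "pairing": stats.as_dict(),
        "n_edges": net.n_edges,
        "total_pairs_used": net.total_pairs_used,
        "n_partitions": len(partitions),
        "n_ccs": len(ccs),
        "cc_size_classes": _cc_size_class_counts(ccs),
        "n_evaluable_ccs": len(evaluable_ids),
        "n_recursed": len(to_recurse),
        "n_final_bins": len(bins),
        "bins_per_tier": {
            tier: sum(1 for b in bins if (b.tier or "unevaluated") == tier)
            for tier in ("high", "medium", "low", "contaminated", "unevaluated")
        },
    }
    return PipelineResult(
        catalog=catalog,
        network=net,
        partitions=partitions,
        ccs=ccs,
        bins=bins,
        recursed_parents=to_recurse,
        pairing_stats=stats,
        rna_profiles=rna_profiles,
        summary=summary,
        manifest=manifest,
    )


def run_pipeline(
    config: PipelineConfig,
    out_dir: Union[str, Path],
    pairs_path: Union[str, Path],
    contigs_fasta: Optional[Union[str, Path]] = None,
    nodes_path: Optional[Union[str, Path]] = None,
    markers_path: Optional[Union[str, Path]] = None,
    rna_path: Optional[Union[str, Path]] = None,
) -> PipelineResult:
    """File-based pipeline: read inputs, run all stages, write everything.

    The contig catalog comes from a nodes TSV (contig_id, length,
    coverage) and/or a FASTA (lengths only); coverage is required for
    normalization. ``pairs_path`` is the 7-column pairs TSV or a SAM/BAM.
    Marker and RNA annotation TSVs are optional; without them binning
    stops at CC extraction.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        if nodes_path is not None:
            catalog = pio.read_nodes(nodes_path)
        elif contigs_fasta is not None:
            catalog = pio.catalog_from_fasta(contigs_fasta)
        else:
            raise StageError("Align", "need a nodes TSV or a contigs FASTA")
        pairs_path = Path(pairs_path)
        if not pairs_path.exists():
            raise StageError("Align", f"pairs file {pairs_path} does not exist")
        if pairs_path.suffix in (".sam", ".bam"):
            from proxibin.network import read_sam_alignments

            alignments = list(read_sam_alignments(str(pairs_path)))
        else:
            alignments = pio.read_pairs_tsv(pairs_path)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 — re-raise with the stage named
        raise StageError("Align", str(exc)) from exc

    markers = None
    rna_features = None
    if markers_path is not None:
        markers = MarkerTable.from_frame(pd.read_csv(markers_path, sep="\t"))
    if rna_path is not None:
        rna_features = pd.read_csv(rna_path, sep="\t")

    result = run_pipeline_objects(
        catalog, alignments, config, markers=markers, rna_features=rna_features
    )

    pio.write_network(result.network, out_dir / "network.txt", sidecar=out_dir / "network.raw.tsv")
    pio.write_nodes(result.catalog, out_dir / "nodes.tsv")
    pio.write_partition_table(result.partitions, out_dir / "partitions.tsv")
    pio.write_cc_table(result.ccs, out_dir / "cc.tsv")
    pio.write_bin_table(result.bins, out_dir / "bins.tsv")
    pio.write_quality_table(result.bins, result.rna_profiles, out_dir / "quality.tsv")
    result.summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    config.to_file(out_dir / "config.txt")
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=2) + "\n")
    return result
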