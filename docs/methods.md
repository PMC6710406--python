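# Methods

## The model

Proximity-ligation (meta3C / Hi-C) libraries capture physical collisions
between DNA loci. Because chromatin is confined to cells, two loci in the
same cell collide orders of magnitude more often than loci in different
cells. Mapped onto a metagenome assembly, the read pairs of such a library
therefore connect contigs of the same genome far more densely than contigs
of different genomes. proxibin treats this as a community-detection
problem on a weighted contig graph.

### Contact network

Both mates of each pair are treated as independent single-end alignments.
A pair contributes one edge count iff both mates are unambiguous
(no secondary/supplementary record, a single primary record per mate),
both have mapping quality ≥ 20, and they hit two *different* contigs.
Contigs shorter than 500 bp are removed first. The raw weight of edge
(a, b) is the number of bridging pairs; the working weight is

    w(a, b) = n(a, b) / sqrt(cov(a) · cov(b))

— the raw count divided by the geometric mean of the contigs' mean read
depths. This removes the first-order abundance effect: without it,
abundant genomes would dominate modularity optimization simply because
they were sequenced deeper. Coverage is mean depth, aligned bases over
contig length; intra-contig (cis) pairs do not form edges but their
aligned bases *do* count toward coverage — they are sequencing signal,
and excluding them would bias depth downward on long contigs.

Boundary conventions, fixed in one place and tested exhaustively: length
and mapq thresholds discard only *strictly* smaller values (a 500 bp
contig and a mapq-20 mate are kept). Edges with a zero-coverage endpoint
are undefined under the formula and dropped with a warning rather than
patched with a pseudo-count. Self-pairs are excluded from edges but
counted, since their fraction is a useful library diagnostic.

### Iterated Louvain and core communities

A single Louvain run greedily maximizes weighted Newman–Girvan modularity
(resolution 1) and depends on the node visit order. Rather than trusting
one run, the engine runs it many times (default 400) with seeds derived
as `base_seed + run_index`, and pools contigs that share a community in
*every one of the first 100 runs* into core communities (CCs) — the meet,
i.e. common refinement, of the run partitions. The meet is computed by
grouping contigs on their label vector across runs (O(n·runs)), and is
checked in the tests against an O(n²·runs) pairwise co-membership
closure. Two algebraic laws follow from the construction and are asserted
as properties: the CC partition refines every input partition, and adding
runs can only split CCs, never merge them.

Because run seeds are arithmetic in the run index, the CCs obtained from
running exactly 100 iterations are identical to those from pooling the
first 100 of 400; the fast paths in the tests and the acceptance script
exploit this instead of paying for runs the meet never looks at. The
per-run modularity and the CC co-cluster score (in how many runs two CCs
shared a label) are logged for diagnostics.

Louvain runs on the full graph; isolated contigs become singleton CCs and
fall out of evaluation via the size filter. CC ids are assigned by
decreasing total bp, ties broken by the lexicographically smallest member
id, so ids are deterministic. The clustering engine is the seeded Louvain
of networkx; tests verify its output independently (local-optimality
check, closed-form modularity values) rather than assuming it.

### Bin evaluation and recursion

CCs above 500 kb (strict) are scored for completeness and contamination.
The internal model is the classic single-copy-marker argument:

    completeness  = 100 · |markers present ≥ 1×| / |marker set|
    contamination = 100 · Σ_m max(0, copies_m − 1) / |marker set|

This deliberately simplifies lineage-aware tools (no lineage-specific
marker sets, no collocated-set correction); a reader for CheckM's tabular
output allows substituting real scores while keeping all downstream logic
identical. A CC is a valid bin when contamination < 10% (strict).

CCs that are largely complete yet contaminated — completeness > 70% AND
contamination > 10%, both strict — usually pool several related genomes
bridged by conserved sequence. These are re-partitioned on their own
sub-network with a short iteration (10 runs, all pooled in the meet), and
the resulting sub-CCs replace the parent. Recursion depth defaults to 1
(a `max_depth` knob exists); sub-CC membership never crosses the parent
boundary, and the union of sub-CCs is asserted equal to the parent.

### MIMAG tiers

high: contamination < 5, completeness > 90 (strict), ≥ 18 distinct tRNAs
and presence of 5S, 16S and 23S rRNA; medium: contamination < 10,
completeness ≥ 50; low: contamination < 10, completeness < 50; at ≥ 10%
contamination a bin is `contaminated`. The RNA criteria apply only to the
high tier, per the MIMAG standard; tiers are mutually exclusive by
construction and monotone in both metrics (property-tested). Small CCs
(≤ 500 kb) still appear in the bin table with empty quality fields and
tier `unevaluated`.

## The synthetic generator

The generator emulates only what the method consumes: for every contig
pair, the read-pair count is Poisson with mean

    r · (len_a/L0)(len_b/L0) · sqrt(cov_a · cov_b)/C0

where r is `intra_rate` (default 5.0) when the contigs share a host
genome and `inter_rate` (default 0.02) otherwise, and L0, C0 are the
community's reference contig length (20 kb) and coverage (10×). Quoting
the rates at reference scale makes `intra_rate` read as "expected pairs
for a typical same-genome contig pair". Carrying exactly the
sqrt(cov·cov) factor that normalization divides out means normalized
intra-genome weights are approximately flat, so the planted structure is
analytically predictable. Genome abundances are lognormal (σ = 0.5,
summing to 1); contig lengths lognormal (median ≈ 16.7 kb, floor 100 bp);
per-contig depth carries lognormal noise (σ = 0.2). A configurable
fraction of read pairs is emitted with a low-mapq or ambiguous mate to
exercise the alignment filters. Mobile elements are contigs hosted by
several genomes: they contact *all* their hosts at the intra rate, which
is exactly how conserved sequences weld genomes into one contaminated CC
(`bridge_groups` plants such bridges deliberately). Each genome carries
one copy of every marker in a universal 100-marker set, 20 distinct tRNA
isotypes, and all three rRNA genes, scattered uniformly over its contigs.

What the generator does *not* model: actual nucleotide sequence (FASTA
output is uniform-random ACGT), restriction-fragment geometry, the
distance dependence of cis contacts, chimeric contigs, and read-level
errors. Passing tests therefore demonstrate that the engine correctly
recovers planted modular structure under Poisson sampling noise — not
that any particular real library will be as clean. The default study
conditions (10 genomes × 50 contigs, rate ratio 250) make recovery
reliably achievable; real communities differ mainly through shared
sequence and uneven coverage, which the shared-contig and bridge
machinery probes directly.

## Numerical and design choices

- **Seeding.** All randomness flows from one seed: run i of the Louvain
  iteration uses `base_seed + i`; recursion on CC k uses
  `base_seed + 100000 + k`. Identical seed and config reproduce every
  output file byte for byte (tested).
- **Weight serialization.** `network.txt` writes weights with `repr`, and
  the nodes table uses `%.17g` with round-trip float parsing, so a
  write/read cycle is bit-stable.
- **Degenerate inputs.** An edgeless (sub-)network partitions into
  singletons with modularity defined as 0; an empty catalog after
  filtering aborts the pipeline with the stage named; unknown contigs in
  a pair stream are dropped with a warning and counted.
- **Duplicate handling.** Input is assumed PCR-deduplicated upstream (as
  ligation-tag protocols do); an optional `dedup` flag removes pairs with
  identical mate coordinates.
- **Problem sizes.** The test suite and the acceptance script run the
  default 10 × 50 community with 100 Louvain iterations (equivalent CCs
  to the 400/100 default, see above) and a 3-genome bridged community for
  the recursion study; these sizes give stable statistics at desk scale.

## Known limitations

- The marker model ignores lineage-specific marker sets, so absolute
  completeness/contamination on real data should come from CheckM via the
  provided reader; the thresholds and tier logic are unchanged either way.
- One level of recursion (the default) cannot resolve nested
  contamination (a sub-CC that itself pools genomes); raise `max_depth`
  if needed.
- Louvain's resolution limit means very small genomes embedded in a huge
  network may not separate at resolution 1; the iterate-and-intersect
  design mitigates the stochasticity of single runs but not the
  resolution limit itself.
- Contigs shared between genomes are assigned to exactly one bin (or
  excluded into small CCs); multi-assignment of mobile elements is out of
  scope.
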