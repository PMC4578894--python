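# Methods

## Model

`semascaf` post-processes a de novo transcriptome assembly. Its input is a
BLAST tabular search of draft contigs and scaffolds ("fragments") against
an annotated protein database; every retained hit is an undirected edge of
a bipartite graph whose vertex classes are fragment ids and protein ids.
The central modeling assumption is that two fragments hitting the same
protein — or proteins linked through shared fragments — derive from the
same transcribed gene (or gene family), so each connected component of the
graph is reported as one "super-contig" cluster. The assumption fails in a
known, accepted way: paralogous genes and splice forms sharing homology are
merged into one cluster. Fragments with no sub-threshold hit appear in no
cluster at all — the output deliberately covers only the annotatable part
of the transcriptome.

Fragment and protein identifiers must occupy disjoint namespaces within a
run (checked at load): an id appearing on both sides would silently fuse
unrelated components.

## Filtering

Two cleanups precede clustering:

* **E-value threshold**, default `0.001`, *inclusive* (a hit at exactly the
  cutoff is kept; only strictly weaker hits are excluded). The threshold
  suppresses hits arising from low-complexity regions or shared short
  motifs; it is a user-facing parameter because the right stringency
  depends on the database and the divergence of the study organism.
* **Duplicate collapse.** BLAST reports one line per aligned region, so a
  fragment–protein pair often appears several times. Duplicates are
  collapsed to a single edge per `(query, subject)` pair; the surviving
  representative is the line with the smallest e-value (ties: larger bit
  score, then first occurrence). Which line survives cannot change the
  partition — all duplicates connect the same two vertices — but taking the
  minimum makes the per-cluster nearest-homolog e-value exact rather than
  dependent on input order.

The two operations commute (the surviving representative is the pair
minimum either way), and provenance counts (raw = retained + removed by
threshold + removed as duplicates) are carried on the edge table and
logged.

## Clustering

Edges start with labels equal to their 1-based input positions. One
iteration ("sweep") replaces every edge's label with the minimum label over
its *closed neighborhood* — itself plus all edges sharing its query or its
subject vertex. Iterations repeat until a sweep changes nothing; labels are
then renumbered to the consecutive range `1..K`, smallest converged label
first. Monotonicity (labels never increase, bounded below by 1) guarantees
termination; at the fixpoint, two edges have equal labels exactly when they
are connected, so the partition equals the connected components of the
bipartite graph.

Numerical/implementation choices:

* **Synchronous sweeps.** New labels are computed from a snapshot of the
  labels at sweep start (via a per-vertex minimum computed once per sweep,
  `O(E)` per iteration rather than the naive all-pairs `O(E²)`). Sweep
  outcome — including the recorded iteration count — is therefore
  independent of edge enumeration order and of partitioning the sweep
  across `--workers W` contiguous equal shares, for every `W ≥ 1`. The
  worker splitting is executed deterministically in-process; the contract
  that matters (result invariance under equal-share partitioning) is
  tested, not the scheduling mechanics.
* **Iteration count** (`n_iterations`) counts every sweep executed,
  including the final one that detects the fixpoint. It is a data-dependent
  diagnostic — roughly the edge-adjacency eccentricity of the
  smallest-labeled edge within its component — and is logged, never
  asserted against.
* A brute-force **union-find oracle** (`oracle_components`) computes the
  same partition by a different route. It exists for verification: tests
  hold propagation and oracle equal on randomized instances and
  additionally cross-check the oracle against `networkx` connected
  components, keeping the three routes independent.

## Annotation

Per cluster: member fragments, member proteins, edge count (both membership
sizes are reported, since "cluster size" is ambiguous between edges and
fragments), the nearest homolog, and edge-weight statistics. The nearest
homolog is the subject of the cluster's minimum-e-value edge, with
deterministic tie-breaking (larger bit score, then lexicographically
smallest subject id) so output is platform-independent.

Edge "length" is reported as the weight `−log10(e-value)`, capped at 300
(the cap absorbs BLAST's underflow-to-zero e-values; 1e-300 is near the
smallest normal double). The transform makes min/max/mean finite and
monotone in evidence strength — a *longer* edge weight means a *stronger*
hit. The per-cluster min/max/mean of this weight summarize how confidently
the cluster hangs together.

## Quantification

Assemblers such as SOAPdenovo record which raw read was placed on which
contig. Those records, de-duplicated to one per `(read, contig)` pair, are
tallied per fragment; a contig listed in an optional contig→scaffold
membership table contributes to its scaffold's tally instead (the scaffold,
not the contig, is then the BLAST query fragment). Cluster counts are sums
over member fragments. Conservation holds by construction: cluster totals
plus the unassigned total (reads on fragments outside every cluster) equal
the record count.

Open design points resolved here: a read matching contigs in *different*
clusters is counted once in each — multi-mapping is not resolved, the
estimate is explicitly crude — and the number of such reads is reported so
users can judge the inflation. Paired-end mates are independent records;
there is no fragment-level pairing, no length normalization and no
TPM/FPKM: the intended use is ranking transcripts into broad expression
categories.

Read-on-contig file layouts vary by assembler version, so parsing goes
through a small dialect registry (`soap`: whitespace-separated read, contig,
position, extras ignored; `tsv2col`: read, contig). Unknown dialects fail
with the registered list.

## Synthetic data generator

The generator plants `n_components` vertex-disjoint bipartite components
(defaults: 50 components, 2–6 fragments and 1–4 proteins each, connected by
a random bipartite spanning tree plus ~50% extra within-component edges),
then injects the two noise classes the filter must absorb: duplicate lines
for existing pairs (rate 0.15) and super-threshold hits between arbitrary
vertices (rate 0.10). True-edge e-values are log-uniform on
`[1e-50, 1e-4]`, noise on `[1e-2, 1]`; the decade of clearance on each side
of the 0.001 cutoff makes the planted partition unambiguous ground truth
after filtering. Read records are Poisson per fragment (mean 20, the order
of per-transcript coverage in a small MiSeq-scale project); optional orphan
fragments carry reads but no hit, exercising the unassigned path. With
`merge_noise_rate > 0`, sub-threshold edges may join components — the
planted partition is then intentionally broken and tests compare against
the union-find oracle instead. Everything is driven by one
`numpy.random.default_rng(seed)`, so instances are byte-reproducible.

What the generator does *not* emulate: nucleotide sequences, alignment
score statistics consistent with the e-values, sequencing error, coverage
bias, or realistic component size distributions (real data has a handful of
giant components; the generator's are small and uniform). Passing tests
therefore demonstrate the graph algorithms and bookkeeping are exact on the
modeled structure — not that biological clusters will be correct, which
depends entirely on BLAST hit quality and database coverage.

## Problem sizes

Randomized verification uses 100 generated instances for oracle equivalence
(most a few hundred edge lines, every tenth ~10⁴) and 100 seeds for
planted-truth recovery, with a separate ~10⁵-edge smoke test guarding
against quadratic regressions. These sizes give dense coverage of the
combinatorics while keeping the default suite fast; the algorithms are
linear per sweep, so behavior at millions of edges differs only in wall
time.

## Known limitations

* Paralog/splice-form collapse (inherent to the model; separating them is
  explicitly out of scope).
* One noisy cross-family BLAST hit below the cutoff can chain two genuine
  clusters into one; the e-value threshold is the only defense.
* Expression counts inherit every multi-mapping and coverage bias of the
  upstream read placement; they are ordinal evidence, not estimates of
  transcript abundance in the statistical sense.
* The unclustered remainder (fragments with no retained hit) is counted and
  logged but otherwise dropped; novel genes with no database homolog are
  invisible to this method.
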