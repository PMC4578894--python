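# semascaf

Homology-guided "semantic" super-scaffolding of de novo transcriptome
assemblies — for researchers working on organisms with no reference genome.

De novo assemblers (SOAPdenovo-Trans, Trinity, Oases, ...) join reads only
where nucleotide context overlaps, so a low-coverage or low-quality RNA-seq
project ends with hundreds of thousands of short fragments instead of a
gene-sized transcript catalog. Many of those fragments, however, encode
parts of the *same protein*. `semascaf` exploits that: it takes the standard
tabular output of a BLAST search of the draft contigs/scaffolds against a
protein database (e.g. SwissProt), treats every hit as an edge between a
fragment vertex and a protein vertex, and merges the connected components of
that bipartite graph into annotated **super-contig clusters** — bracing
fragments that share no sequence overlap but hit the same, or mutually
homologous, database proteins.

## Method

Given hits \(h = (q, s, \ldots, e)\) with query fragment \(q\), database
protein \(s\) and expectation value \(e\):

1. **Filter.** Discard hits with \(e > 10^{-3}\) (cutoff configurable,
   inclusive: \(e = 10^{-3}\) is kept) and collapse *duplicated edges* —
   multiple hit lines for the same \((q, s)\) pair, which describe different
   homologous regions of one pair — keeping the lowest-e-value line.
2. **Cluster.** Label edges \(1 \ldots N\) by input position. Each sweep
   assigns every pair of edges sharing a vertex the smaller of their two
   labels (an edge pair with labels 45 and 328 both become 45); sweeps
   repeat until nothing changes, then labels are renumbered to the gapless
   range \(1 \ldots K\). The fixpoint is exactly the connected components of
   the fragment–protein graph. Sweeps are synchronous, so the result is
   independent of edge order and of how the work is split across workers.
3. **Annotate.** Each cluster reports its *nearest homolog* — the subject of
   its minimum-e-value hit — plus membership and edge-weight statistics,
   where the weight of an edge is \(-\log_{10} e\) (capped at 300).
4. **Quantify.** Read→contig placements recorded by the assembler are
   tallied per fragment (optionally rolled up contig→scaffold) and summed
   over each cluster's members: a crude relative-abundance estimate that
   sorts transcripts into highly / intermediately / lowly expressed.

The known tradeoff is paralog collapse: closely related paralogs and splice
forms may merge into one cluster. See `docs/methods.md` for assumptions,
parameter choices and limitations.

## Worked example

`examples/cluster_and_annotate.py` clusters eight toy BLAST hits: fragments
c1–c3 are braced through proteins P10/P20, c4–c5 through P30, one line is a
duplicate and one is too weak to keep:

```
8 raw hits -> 6 edges (1 above cutoff, 1 duplicates removed)
2 clusters after 3 propagation sweeps

cluster 1: fragments [c1,c2,c3] nearest homolog sp|P10 (e=1e-40), 4 edges, mean weight 22.0
cluster 2: fragments [c4,c5] nearest homolog sp|P30 (e=1e-30), 2 edges, mean weight 18.0
```

The two clusters are the reconstructed transcripts; each nearest homolog
(the cluster's lowest-e-value hit) is the annotation proxy you would carry
into downstream functional analysis, and the mean weight is the average
\(-\log_{10} e\) of the cluster's edges — larger means stronger homology
evidence. The other examples show quantification
(`examples/quantify_expression.py`) and the planted-truth fixture generator
(`examples/simulate_fixture.py`).

## Command line

```sh
semascaf simulate --components 50 --seed 1 --out-dir fixtures/
semascaf annotate --blast fixtures/hits.tsv --reads fixtures/reads.txt \
                  --out clusters.tsv
semascaf quantify --reads reads.txt --dialect soap --clusters clusters.tsv \
                  --out quantified.tsv
semascaf stats --clusters clusters.tsv
```

All outputs are UTF-8 TSV with one `#`-prefixed header line; provenance
(raw / filtered / deduplicated edge counts, cluster count, iteration count,
unassigned reads) is logged to stderr. Options may come from a YAML file
via `--config`; explicit flags win.

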