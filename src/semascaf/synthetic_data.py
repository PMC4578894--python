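"""Planted-truth fixture generator for the whole pipeline.

Builds a random fragment–protein homology graph with a known component
structure, then layers on the two kinds of noise the edge filter must
absorb: duplicated BLAST lines (same query/subject pair, different aligned
region) and super-threshold hits (e-value above the cutoff).  True-edge
e-values are drawn log-uniform in [1e-50, 1e-4] and noise e-values in
[1e-2, 1], so the 0.001 cutoff separates them unambiguously and the
planted partition is exact ground truth after filtering.

Read→contig records are generated per fragment with Poisson counts, giving
known per-component read totals.  Optionally, sub-threshold "merge noise"
edges between components can be enabled, in which case the planted
partition is no longer the truth and callers should compare against the
union-find oracle instead.

The generator emulates the *shape* of real BLAST tabular data (column
layout, e-value ranges, duplicate hits), not its content: there are no
nucleotide sequences, no alignment score statistics, and no sequencing
error model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .blast_io import HomologyEdge, ReadMatchRecord, write_blast_tabular

__all__ = ["GeneratorParams", "PlantedInstance", "generate", "write_instance"]


@dataclass(frozen=True)
class GeneratorParams:
    """Settings for one planted instance.

    Defaults model a small but structured draft-assembly search: a few
    dozen components, each bracing 2–6 assembly fragments through 1–4
    database proteins, with 15% duplicated hit lines, 10% super-threshold
    noise hits, and Poisson(20) reads per fragment.
    """

    n_components: int = 50
    fragments_per_component: tuple[int, int] = (2, 6)
    proteins_per_component: tuple[int, int] = (1, 4)
    extra_edge_rate: float = 0.5
    duplicate_rate: float = 0.15
    superthreshold_rate: float = 0.10
    merge_noise_rate: float = 0.0
    true_evalue_range: tuple[float, float] = (1e-50, 1e-4)
    noise_evalue_range: tuple[float, float] = (1e-2, 1.0)
    reads_per_fragment_mean: float = 20.0
    n_orphan_fragments: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 0:
            raise ValueError("n_components must be >= 0")
        for name in ("duplicate_rate", "superthreshold_rate",
                     "merge_noise_rate", "extra_edge_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.reads_per_fragment_mean < 0:
            raise ValueError("reads_per_fragment_mean must be >= 0")


@dataclass(frozen=True)
class PlantedInstance:
    """A generated fixture with its ground truth.

    ``true_partition`` maps every planted fragment to its component id
    (1-based); ``true_counts`` gives the read total per component.  Orphan
    fragments (reads but no homology hit) appear in neither — their reads
    are the expected "unassigned" total, available as ``orphan_read_total``.
    """

    edges: tuple[HomologyEdge, ...]
    true_partition: dict[str, int]
    read_records: tuple[ReadMatchRecord, ...]
    true_counts: dict[int, int]
    orphan_read_total: int
    params: GeneratorParams


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10.0 ** rng.uniform(math.log10(lo), math.log10(hi)))


def _make_edge(
    rng: np.random.Generator, query: str, subject: str, evalue: float
) -> HomologyEdge:
    length = int(rng.integers(30, 200))
    mismatches = int(rng.integers(0, max(1, length // 4)))
    q_start = int(rng.integers(1, 500))
    s_start = int(rng.integers(1, 300))
    return HomologyEdge(
        query_id=query,
        subject_id=subject,
        percent_identity=round(100.0 * (length - mismatches) / length, 2),
        alignment_length=length,
        mismatches=mismatches,
        gap_opens=int(rng.integers(0, 3)),
        q_start=q_start,
        q_end=q_start + length - 1,
        s_start=s_start,
        s_end=s_start + length - 1,
        evalue=evalue,
        bit_score=round(float(rng.uniform(30.0, 400.0)), 1),
    )


def generate(params: GeneratorParams) -> PlantedInstance:
    """Generate a planted instance; deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)

    edges: list[HomologyEdge] = []
    true_partition: dict[str, int] = {}
    component_fragments: dict[int, list[str]] = {}
    all_proteins: list[str] = []

    for comp in range(1, params.n_components + 1):
        n_frag = int(rng.integers(params.fragments_per_component[0],
                                  params.fragments_per_component[1] + 1))
        n_prot = int(rng.integers(params.proteins_per_component[0],
                                  params.proteins_per_component[1] + 1))
        fragments = [f"frag{comp}_{i}" for i in range(1, n_frag + 1)]
        proteins = [f"sp|P{comp}_{j}" for j in range(1, n_prot + 1)]
        component_fragments[comp] = fragments
        all_proteins.extend(proteins)
        for f in fragments:
            true_partition[f] = comp

        # random bipartite spanning tree: each vertex after the first two
        # attaches to a placed vertex of the opposite type
        placed_frags = [fragments[0]]
        placed_prots = [proteins[0]]
        comp_edges = [(fragments[0], proteins[0])]
        rest = fragments[1:] + proteins[1:]
        rng.shuffle(rest)
        for vertex in rest:
            if vertex.startswith("frag"):
                partner = placed_prots[int(rng.integers(len(placed_prots)))]
                comp_edges.append((vertex, partner))
                placed_frags.append(vertex)
            else:
                partner = placed_frags[int(rng.integers(len(placed_frags)))]
                comp_edges.append((partner, vertex))
                placed_prots.append(vertex)

        # extra within-component edges thicken the graph beyond a tree
        n_extra = int(rng.binomial(len(comp_edges), params.extra_edge_rate))
        existing = set(comp_edges)
        for _ in range(n_extra):
            pair = (fragments[int(rng.integers(n_frag))],
                    proteins[int(rng.integers(n_prot))])
            if pair not in existing:
                comp_edges.append(pair)
                existing.add(pair)

        for query, subject in comp_edges:
            evalue = _log_uniform(rng, *params.true_evalue_range)
            edges.append(_make_edge(rng, query, subject, evalue))

    all_fragments = [f for frags in component_fragments.values() for f in frags]

    # duplicated BLAST lines: same pair, different aligned region, weaker hit
    n_dup = int(rng.binomial(len(edges), params.duplicate_rate)) if edges else 0
    for _ in range(n_dup):
        base = edges[int(rng.integers(len(edges)))]
        evalue = _log_uniform(rng, base.evalue, params.true_evalue_range[1])
        edges.append(_make_edge(rng, base.query_id, base.subject_id, evalue))

    # super-threshold noise: removed by the filter, so endpoints are free
    n_noise = int(rng.binomial(len(edges), params.superthreshold_rate)) if edges else 0
    for _ in range(n_noise):
        query = all_fragments[int(rng.integers(len(all_fragments)))]
        subject = all_proteins[int(rng.integers(len(all_proteins)))]
        evalue = _log_uniform(rng, *params.noise_evalue_range)
        edges.append(_make_edge(rng, query, subject, evalue))

    # optional sub-threshold merge noise between components: breaks the
    # planted truth on purpose (compare against the oracle instead)
    if params.merge_noise_rate > 0 and params.n_components >= 2:
        n_merge = int(rng.binomial(len(edges), params.merge_noise_rate))
        for _ in range(n_merge):
            query = all_fragments[int(rng.integers(len(all_fragments)))]
            subject = all_proteins[int(rng.integers(len(all_proteins)))]
            evalue = _log_uniform(rng, *params.true_evalue_range)
            edges.append(_make_edge(rng, query, subject, evalue))

    order = rng.permutation(len(edges))
    edges = [edges[i] for i in order]

    # reads: Poisson per fragment; orphans have reads but no homology hit
    read_records: list[ReadMatchRecord] = []
    true_counts: dict[int, int] = {c: 0 for c in component_fragments}
    read_no = 0
    for comp, fragments in component_fragments.items():
        for fragment in fragments:
            n_reads = int(rng.poisson(params.reads_per_fragment_mean))
            true_counts[comp] += n_reads
            for _ in range(n_reads):
                read_no += 1
                read_records.append(ReadMatchRecord(
                    f"read{read_no}", fragment, int(rng.integers(0, 1000))
                ))
    orphan_total = 0
    for i in range(1, params.n_orphan_fragments + 1):
        n_reads = int(rng.poisson(params.reads_per_fragment_mean))
        orphan_total += n_reads
        for _ in range(n_reads):
            read_no += 1
            read_records.append(ReadMatchRecord(
                f"read{read_no}", f"orph{i}", int(rng.integers(0, 1000))
            ))

    return PlantedInstance(
        edges=tuple(edges),
        true_partition=true_partition,
        read_records=tuple(read_records),
        true_counts=true_counts,
        orphan_read_total=orphan_total,
        params=params,
    )


def write_instance(instance: PlantedInstance, out_dir: str | Path) -> dict[str, Path]:
    """Write an instance as text fixtures: hits.tsv, reads.txt, truth.tsv.

    ``truth.tsv`` holds the planted fragment→component map; per-component
    read totals go to ``truth_counts.tsv``.  Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "hits": out / "hits.tsv",
        "reads": out / "reads.txt",
        "truth": out / "truth.tsv",
        "truth_counts": out / "truth_counts.tsv",
    }
    write_blast_tabular(instance.edges, paths["hits"])
    with open(paths["reads"], "w", encoding="utf-8") as handle:
        for r in instance.read_records:
            handle.write(f"{r.read_id}\t{r.contig_id}\t{r.position}\n")
    with open(paths["truth"], "w", encoding="utf-8") as handle:
        handle.write("#fragment\tcomponent\n")
        for fragment in sorted(instance.true_partition):
            handle.write(f"{fragment}\t{instance.true_partition[fragment]}\n")
    with open(paths["truth_counts"], "w", encoding="utf-8") as handle:
        handle.write("#component\tread_count\n")
        for comp in sorted(instance.true_counts):
            handle.write(f"{comp}\t{instance.true_counts[comp]}\n")
    return paths
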