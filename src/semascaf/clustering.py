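"""Iterative min-label propagation over the fragment–protein homology graph.

Each retained BLAST hit is an edge joining a query-fragment vertex to a
database-protein vertex.  Edges start labeled 1..N by input position; each
sweep assigns every pair of edges sharing a vertex the smaller of their two
labels, and sweeps repeat until no label changes.  The fixpoint is exactly
the connected components of the bipartite graph, so fragments that hit the
same protein — or proteins bridged by a shared fragment — end up in one
super-contig cluster even with no nucleotide overlap.

Sweeps are synchronous: every new label is computed from a snapshot of the
labels at the start of the sweep (the minimum over the edge's closed
neighborhood).  This makes the result independent of the order in which
edges are compared and of how the comparison work is partitioned across
workers, which is the correctness contract behind running the sweep in
equal-share parallel chunks.

A textbook union-find oracle (:func:`oracle_components`) computes the same
partition by a different route; tests hold the two equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .blast_io import HomologyEdge
from .edge_filter import EdgeTable

__all__ = [
    "ClusterAssignment",
    "propagate_once",
    "cluster_edges",
    "relabel_consecutive",
    "oracle_components",
]


@dataclass(frozen=True)
class ClusterAssignment:
    """Result of clustering: per-edge labels plus derived vertex maps.

    ``labels`` maps the 1-based edge index to its cluster label; after
    :func:`relabel_consecutive` the labels form the gapless range 1..K.
    ``fragment_clusters`` / ``protein_clusters`` map each vertex to its
    (unique) cluster.
    """

    labels: dict[int, int]
    n_iterations: int
    fragment_clusters: dict[str, int]
    protein_clusters: dict[str, int]

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


def _vertex_incidence(
    edges: Sequence[HomologyEdge],
) -> tuple[dict[str, list[int]], dict[str, list[int]]]:
    """Index 1-based edge positions by query vertex and by subject vertex."""
    by_query: dict[str, list[int]] = {}
    by_subject: dict[str, list[int]] = {}
    for idx, edge in enumerate(edges, start=1):
        by_query.setdefault(edge.query_id, []).append(idx)
        by_subject.setdefault(edge.subject_id, []).append(idx)
    return by_query, by_subject


def propagate_once(
    labels: Mapping[int, int],
    edges: EdgeTable | Sequence[HomologyEdge],
    workers: int = 1,
) -> tuple[dict[int, int], bool]:
    """Run one synchronous label-propagation sweep.

    Every edge receives the minimum label over itself and all edges sharing
    either of its vertices, evaluated on the labels as they stood at the
    start of the sweep.  Labels never increase.  Returns the new labels and
    whether any label decreased.

    ``workers`` splits the edge list into that many contiguous equal shares
    whose updates are computed independently from the shared snapshot; the
    result is identical for every ``workers >= 1``.
    """
    edge_list = list(edges)
    if len(labels) != len(edge_list):
        raise ValueError(
            f"labels defined for {len(labels)} edges but table has {len(edge_list)}"
        )
    if workers < 1:
        raise ValueError(f"workers must be >= 1, got {workers}")

    by_query, by_subject = _vertex_incidence(edge_list)
    # min label per vertex, from the snapshot
    vmin_q = {v: min(labels[i] for i in idxs) for v, idxs in by_query.items()}
    vmin_s = {v: min(labels[i] for i in idxs) for v, idxs in by_subject.items()}

    n = len(edge_list)
    new_labels: dict[int, int] = {}
    share = -(-n // workers) if n else 0  # ceil division; empty table → no shares
    for w in range(workers):
        lo, hi = w * share, min((w + 1) * share, n)
        for pos in range(lo, hi):
            idx = pos + 1
            edge = edge_list[pos]
            new_labels[idx] = min(
                labels[idx], vmin_q[edge.query_id], vmin_s[edge.subject_id]
            )
    changed = any(new_labels[i] < labels[i] for i in new_labels)
    return new_labels, changed


def cluster_edges(edges: EdgeTable, workers: int = 1) -> ClusterAssignment:
    """Cluster a filtered, de-duplicated edge table into super-contigs.

    Initial labels are the 1-based edge indices; sweeps repeat until a
    sweep changes nothing, then labels are renumbered to the consecutive
    range 1..K.  ``n_iterations`` counts every sweep executed, including
    the final fixed-point check.  An empty table yields an empty
    assignment (K = 0).
    """
    edge_list = list(edges)
    labels = {idx: idx for idx in range(1, len(edge_list) + 1)}

    n_iterations = 0
    if edge_list:
        while True:
            labels, changed = propagate_once(labels, edge_list, workers=workers)
            n_iterations += 1
            if not changed:
                break

    assignment = ClusterAssignment(
        labels=labels,
        n_iterations=n_iterations,
        fragment_clusters={},
        protein_clusters={},
    )
    return relabel_consecutive(assignment, edge_list)


def relabel_consecutive(
    assignment: ClusterAssignment,
    edges: EdgeTable | Sequence[HomologyEdge],
) -> ClusterAssignment:
    """Renumber converged labels to 1..K, preserving their ascending order.

    The cluster whose converged label is smallest becomes cluster 1, and so
    on; the partition itself is unchanged.  Also (re)derives the
    fragment→cluster and protein→cluster maps.
    """
    edge_list = list(edges)
    distinct = sorted(set(assignment.labels.values()))
    rank = {old: new for new, old in enumerate(distinct, start=1)}
    labels = {idx: rank[lab] for idx, lab in assignment.labels.items()}

    fragment_clusters: dict[str, int] = {}
    protein_clusters: dict[str, int] = {}
    for idx, edge in enumerate(edge_list, start=1):
        lab = labels[idx]
        fragment_clusters[edge.query_id] = lab
        protein_clusters[edge.subject_id] = lab

    return ClusterAssignment(
        labels=labels,
        n_iterations=assignment.n_iterations,
        fragment_clusters=fragment_clusters,
        protein_clusters=protein_clusters,
    )


class _UnionFind:
    """Union-find with path compression and union by size."""

    def __init__(self) -> None:
        self.parent: dict[str, str] = {}
        self.size: dict[str, int] = {}

    def find(self, x: str) -> str:
        if x not in self.parent:
            self.parent[x] = x
            self.size[x] = 1
            return x
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def oracle_components(
    edges: EdgeTable | Sequence[HomologyEdge],
) -> list[frozenset[str]]:
    """Connected components of the bipartite graph by textbook union-find.

    An independent route to the same partition as :func:`cluster_edges`;
    intended for verification.  Returns one frozenset of vertex ids
    (fragments and proteins mixed) per component.
    """
    uf = _UnionFind()
    for edge in edges:
        uf.union(edge.query_id, edge.subject_id)
    groups: dict[str, set[str]] = {}
    for vertex in uf.parent:
        groups.setdefault(uf.find(vertex), set()).add(vertex)
    return [frozenset(members) for members in groups.values()]
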