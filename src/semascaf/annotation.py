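"""Per-cluster annotation: nearest homolog, membership, edge statistics.

A cluster inherits its identity from the database protein of its strongest
hit — the nearest homolog, chosen by lowest e-value.  Edge "length" is the
homology weight −log10(e-value) (capped at 300 for underflowing e-values),
so a longer edge means stronger similarity; min/max/mean of this weight
summarize how tightly a cluster hangs together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .blast_io import HomologyEdge
from .clustering import ClusterAssignment
from .edge_filter import EdgeTable

__all__ = ["ClusterRecord", "EVALUE_WEIGHT_CAP", "edge_length", "annotate_clusters"]

#: Weight assigned to e-values of zero (or below 1e-300): −log10 capped.
EVALUE_WEIGHT_CAP = 300.0


@dataclass(frozen=True)
class ClusterRecord:
    """One annotated super-contig cluster.

    ``read_count`` is filled by the quantification step and is 0 until
    then.  ``nearest_evalue`` is the minimum e-value over the cluster's
    edges and ``nearest_homolog`` the subject of an edge achieving it.
    """

    cluster_id: int
    member_fragments: frozenset[str]
    member_proteins: frozenset[str]
    nearest_homolog: str
    nearest_evalue: float
    n_edges: int
    edge_len_min: float
    edge_len_max: float
    edge_len_mean: float
    read_count: int = 0

    def with_read_count(self, count: int) -> "ClusterRecord":
        return replace(self, read_count=count)


def edge_length(edge: HomologyEdge) -> float:
    """Homology weight of an edge: −log10(evalue), capped at 300.

    E-values of exactly zero (BLAST underflow) and values below 1e-300
    saturate at the cap.
    """
    if edge.evalue <= 1e-300:
        return EVALUE_WEIGHT_CAP
    return min(-math.log10(edge.evalue), EVALUE_WEIGHT_CAP)


def annotate_clusters(
    assignment: ClusterAssignment, edges: EdgeTable
) -> list[ClusterRecord]:
    """Build one :class:`ClusterRecord` per cluster, ordered by cluster id.

    The nearest homolog is chosen by minimum e-value; ties are broken by
    larger bit score, then by lexicographically smallest subject id, so the
    output is deterministic across platforms.

    Raises
    ------
    ValueError
        If some edge index has no label in the assignment.
    """
    edge_list = list(edges)
    by_cluster: dict[int, list[HomologyEdge]] = {}
    for idx, edge in enumerate(edge_list, start=1):
        if idx not in assignment.labels:
            raise ValueError(f"edge index {idx} has no cluster label")
        by_cluster.setdefault(assignment.labels[idx], []).append(edge)

    records: list[ClusterRecord] = []
    for cluster_id in sorted(by_cluster):
        members = by_cluster[cluster_id]
        best = min(members, key=lambda e: (e.evalue, -e.bit_score, e.subject_id))
        weights = [edge_length(e) for e in members]
        records.append(ClusterRecord(
            cluster_id=cluster_id,
            member_fragments=frozenset(e.query_id for e in members),
            member_proteins=frozenset(e.subject_id for e in members),
            nearest_homolog=best.subject_id,
            nearest_evalue=best.evalue,
            n_edges=len(members),
            edge_len_min=min(weights),
            edge_len_max=max(weights),
            edge_len_mean=sum(weights) / len(weights),
        ))
    return records
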