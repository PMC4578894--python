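"""Crude per-cluster expression estimation from read→contig matches.

Reads placed on contigs by the assembler are tallied per fragment
(optionally rolled up from contigs to their scaffolds first), then every
fragment in a cluster contributes its count to the cluster total.  The
estimate is deliberately crude: no length normalization, no multi-mapping
resolution — its purpose is to sort reconstructed transcripts into highly,
intermediately and lowly expressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .blast_io import ReadMatchRecord
from .clustering import ClusterAssignment

__all__ = [
    "ReadMatchTable",
    "QuantifyResult",
    "count_reads_per_fragment",
    "aggregate_to_clusters",
    "quantify",
    "quantify_cluster_records",
]


@dataclass(frozen=True)
class ReadMatchTable:
    """De-duplicated read→contig records plus optional scaffold membership.

    ``contig_to_scaffold``, when present, must be a function: a contig
    belonging to two scaffolds is rejected at construction.
    """

    records: tuple[ReadMatchRecord, ...]
    contig_to_scaffold: dict[str, str] | None = None

    def __post_init__(self) -> None:
        pairs = {(r.read_id, r.contig_id) for r in self.records}
        if len(pairs) != len(self.records):
            raise ValueError("duplicate (read_id, contig_id) records present")


@dataclass(frozen=True)
class QuantifyResult:
    """Per-cluster read counts plus bookkeeping on reads left out.

    ``unassigned_total`` counts records on fragments outside every cluster;
    ``multi_cluster_reads`` counts reads that hit fragments in more than
    one cluster (each such read is counted once per cluster, so cluster
    totals may sum to more than the distinct read count).
    """

    cluster_counts: dict[int, int]
    unassigned_total: int
    multi_cluster_reads: int = 0


def count_reads_per_fragment(table: ReadMatchTable) -> dict[str, int]:
    """Tally read records per fragment, rolling contigs up to scaffolds.

    A contig listed in the membership table contributes its records to its
    scaffold's count; an unlisted contig counts under its own id.
    Fragments with zero records are absent from the result.
    """
    membership = table.contig_to_scaffold or {}
    counts: dict[str, int] = {}
    for record in table.records:
        fragment = membership.get(record.contig_id, record.contig_id)
        counts[fragment] = counts.get(fragment, 0) + 1
    return counts


def _aggregate(
    counts: Mapping[str, int],
    fragment_clusters: Mapping[str, int],
    cluster_ids: set[int],
) -> QuantifyResult:
    cluster_counts: dict[int, int] = {label: 0 for label in cluster_ids}
    unassigned = 0
    for fragment, count in counts.items():
        label = fragment_clusters.get(fragment)
        if label is None:
            unassigned += count
        else:
            cluster_counts[label] += count
    return QuantifyResult(
        cluster_counts=cluster_counts, unassigned_total=unassigned
    )


def aggregate_to_clusters(
    counts: Mapping[str, int], assignment: ClusterAssignment
) -> QuantifyResult:
    """Sum fragment counts into their clusters.

    Each cluster's count is the sum over its member fragments; counts on
    fragments that belong to no cluster accumulate in ``unassigned_total``.
    Every cluster appears in the result, at count 0 if none of its
    fragments drew a read.  Conservation holds by construction: cluster
    totals plus the unassigned total equal the grand total of the input.
    """
    return _aggregate(
        counts, assignment.fragment_clusters, set(assignment.labels.values())
    )


def _multi_cluster_reads(
    table: ReadMatchTable, fragment_clusters: Mapping[str, int]
) -> int:
    """Number of reads whose contigs land in more than one cluster."""
    membership = table.contig_to_scaffold or {}
    clusters_per_read: dict[str, set[int]] = {}
    for record in table.records:
        fragment = membership.get(record.contig_id, record.contig_id)
        label = fragment_clusters.get(fragment)
        if label is not None:
            clusters_per_read.setdefault(record.read_id, set()).add(label)
    return sum(1 for hit in clusters_per_read.values() if len(hit) > 1)


def quantify(table: ReadMatchTable, assignment: ClusterAssignment) -> QuantifyResult:
    """Full quantification: tally, roll up, aggregate, flag multi-mappers.

    A read whose contigs land in two different clusters is counted once in
    each (multi-mapping is not resolved); ``multi_cluster_reads`` reports
    how many reads did so, so users can judge the resulting inflation.
    """
    counts = count_reads_per_fragment(table)
    result = aggregate_to_clusters(counts, assignment)
    return QuantifyResult(
        cluster_counts=result.cluster_counts,
        unassigned_total=result.unassigned_total,
        multi_cluster_reads=_multi_cluster_reads(
            table, assignment.fragment_clusters
        ),
    )


def quantify_cluster_records(
    table: ReadMatchTable, records: list["ClusterRecord"]
) -> tuple[list["ClusterRecord"], QuantifyResult]:
    """Quantify against an existing annotated cluster table.

    Rebuilds the fragment→cluster map from the records' memberships, so a
    cluster table written to disk can be quantified later without redoing
    the clustering.  Returns the records with ``read_count`` filled, in
    the original order, plus the :class:`QuantifyResult`.
    """
    from .annotation import ClusterRecord  # noqa: F401  (type only)

    fragment_clusters: dict[str, int] = {}
    for record in records:
        for fragment in record.member_fragments:
            fragment_clusters[fragment] = record.cluster_id

    counts = count_reads_per_fragment(table)
    result = _aggregate(
        counts, fragment_clusters, {r.cluster_id for r in records}
    )
    multi = _multi_cluster_reads(table, fragment_clusters)

    updated = [
        r.with_read_count(result.cluster_counts[r.cluster_id]) for r in records
    ]
    return updated, QuantifyResult(
        cluster_counts=result.cluster_counts,
        unassigned_total=result.unassigned_total,
        multi_cluster_reads=multi,
    )
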