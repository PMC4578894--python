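"""E-value thresholding and duplicate-edge removal.

A BLAST search of a fragmented assembly typically reports several local
alignments between the same query fragment and the same database protein
(different homologous regions of one pair).  For graph clustering these
are one edge, so duplicates are collapsed before clustering; likewise hits
weaker than the e-value cutoff (default 0.001, inclusive) carry too little
homology evidence and are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .blast_io import HomologyEdge

__all__ = ["DEFAULT_MAX_EVALUE", "EdgeTable", "filter_by_evalue", "deduplicate"]

#: Default e-value cutoff; hits with larger e-values are not considered.
DEFAULT_MAX_EVALUE = 0.001


def filter_by_evalue(
    edges: list[HomologyEdge], max_evalue: float = DEFAULT_MAX_EVALUE
) -> list[HomologyEdge]:
    """Retain exactly the edges with ``evalue <= max_evalue``, in order.

    The comparison is inclusive: a hit at exactly the cutoff is kept, since
    only hits *higher* than the cutoff are excluded.
    """
    if max_evalue < 0:
        raise ValueError(f"max_evalue must be >= 0, got {max_evalue}")
    return [e for e in edges if e.evalue <= max_evalue]


def deduplicate(edges: list[HomologyEdge]) -> list[HomologyEdge]:
    """Collapse edges sharing the same (query_id, subject_id) pair.

    The surviving representative is the hit with the smallest e-value
    (ties broken by larger bit score, then by first occurrence); output
    order follows the first occurrence of each pair.  Idempotent.
    """
    best: dict[tuple[str, str], HomologyEdge] = {}
    for edge in edges:
        key = (edge.query_id, edge.subject_id)
        incumbent = best.get(key)
        if incumbent is None:
            best[key] = edge
        elif (edge.evalue, -edge.bit_score) < (incumbent.evalue, -incumbent.bit_score):
            best[key] = edge
    return list(best.values())


@dataclass(frozen=True)
class EdgeTable:
    """The filtered, de-duplicated edge list: the clustering substrate.

    Attributes
    ----------
    edges
        Retained edges, in first-occurrence order.
    max_evalue
        The threshold that was applied.
    raw_count, threshold_removed, duplicate_removed
        Provenance counts; ``raw_count`` always equals
        ``len(edges) + threshold_removed + duplicate_removed``.
    """

    edges: tuple[HomologyEdge, ...]
    max_evalue: float = DEFAULT_MAX_EVALUE
    raw_count: int = 0
    threshold_removed: int = 0
    duplicate_removed: int = 0

    def __post_init__(self) -> None:
        if self.raw_count != len(self.edges) + self.threshold_removed + self.duplicate_removed:
            raise ValueError(
                "provenance mismatch: raw_count must equal retained + "
                "threshold_removed + duplicate_removed"
            )

    @classmethod
    def from_raw(
        cls,
        edges: list[HomologyEdge],
        max_evalue: float = DEFAULT_MAX_EVALUE,
    ) -> "EdgeTable":
        """Apply the threshold then deduplicate, recording provenance."""
        raw = len(edges)
        passed = filter_by_evalue(edges, max_evalue)
        retained = deduplicate(passed)
        return cls(
            edges=tuple(retained),
            max_evalue=max_evalue,
            raw_count=raw,
            threshold_removed=raw - len(passed),
            duplicate_removed=len(passed) - len(retained),
        )

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)
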