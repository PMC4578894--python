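"""Readers and writers for the tool's tabular interchange formats.

Three kinds of text tables flow through the pipeline:

* standard 12-column BLAST tabular output (``-outfmt 6``) — one homology
  hit per line, the edges of the fragment–protein graph;
* read-on-contig match records in assembler-specific dialects, optionally
  gzip-compressed — the raw material for abundance estimation;
* the result table of annotated super-contig clusters.

All outputs are UTF-8 TSV with a single ``#``-prefixed header line.
Identifier comparison is case-sensitive and exact throughout.
"""

from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator, TextIO

__all__ = [
    "HomologyEdge",
    "ReadMatchRecord",
    "BlastParseError",
    "read_blast_tabular",
    "write_blast_tabular",
    "read_read_matches",
    "read_scaffold_members",
    "READ_MATCH_DIALECTS",
    "write_cluster_table",
    "read_cluster_table",
]

#: Column order of the standard BLAST tabular layout (outfmt 6).
BLAST_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


class BlastParseError(ValueError):
    """Raised for malformed input lines; carries the 1-based line number."""

    def __init__(self, path: str | Path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(frozen=True, slots=True)
class HomologyEdge:
    """One retained BLAST hit: an edge joining a query fragment to a
    database protein, with the standard tabular alignment statistics.

    Coordinates are 1-based inclusive, as BLAST reports them.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise ValueError("query_id and subject_id must be non-empty")
        if self.evalue < 0:
            raise ValueError(f"evalue must be >= 0, got {self.evalue}")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent_identity must be in [0, 100], got {self.percent_identity}"
            )
        if self.alignment_length < 1:
            raise ValueError(
                f"alignment_length must be >= 1, got {self.alignment_length}"
            )


@dataclass(frozen=True, slots=True)
class ReadMatchRecord:
    """One read placed on one contig by the assembler.

    ``position`` is retained for provenance but ignored by counting.
    """

    read_id: str
    contig_id: str
    position: int = 0

    def __post_init__(self) -> None:
        if not self.contig_id:
            raise ValueError("contig_id must be non-empty")


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _parse_float(field: str, name: str) -> float:
    try:
        value = float(field)
    except ValueError:
        raise ValueError(f"non-numeric {name} field {field!r}") from None
    if math.isnan(value):
        raise ValueError(f"{name} field is NaN")
    return value


def _parse_int(field: str, name: str) -> int:
    try:
        return int(field)
    except ValueError:
        raise ValueError(f"non-integer {name} field {field!r}") from None


def read_blast_tabular(path: str | Path) -> list[HomologyEdge]:
    """Parse standard BLAST tabular output into homology edges.

    Lines beginning with ``#`` are skipped; fields beyond the standard 12
    are tolerated and ignored.  E-values in either ``e`` or ``E`` notation
    are accepted; ``0.0`` is stored as exact zero.  An empty file yields an
    empty list.

    Raises
    ------
    BlastParseError
        On any line with fewer than 12 tab-separated fields or with a
        non-numeric value in a numeric field, naming the line number.
    """
    edges: list[HomologyEdge] = []
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\r\n").rstrip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise BlastParseError(
                    path, lineno,
                    f"expected >= 12 tab-separated fields, found {len(fields)}",
                )
            try:
                edge = HomologyEdge(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=_parse_float(fields[2], "pident"),
                    alignment_length=_parse_int(fields[3], "length"),
                    mismatches=_parse_int(fields[4], "mismatch"),
                    gap_opens=_parse_int(fields[5], "gapopen"),
                    q_start=_parse_int(fields[6], "qstart"),
                    q_end=_parse_int(fields[7], "qend"),
                    s_start=_parse_int(fields[8], "sstart"),
                    s_end=_parse_int(fields[9], "send"),
                    evalue=_parse_float(fields[10], "evalue"),
                    bit_score=_parse_float(fields[11], "bitscore"),
                )
            except ValueError as exc:
                raise BlastParseError(path, lineno, str(exc)) from None
            edges.append(edge)
    _check_disjoint_namespaces(edges, path)
    return edges


def _check_disjoint_namespaces(
    edges: Iterable[HomologyEdge], path: str | Path
) -> None:
    # Fragment and protein ids live in disjoint namespaces within one run;
    # an overlap would silently merge unrelated clusters.
    queries = {e.query_id for e in edges}
    subjects = {e.subject_id for e in edges}
    shared = queries & subjects
    if shared:
        sample = ", ".join(sorted(shared)[:5])
        raise ValueError(
            f"{path}: {len(shared)} identifier(s) appear as both query fragment "
            f"and database protein (e.g. {sample}); namespaces must be disjoint"
        )


def write_blast_tabular(edges: Iterable[HomologyEdge], path: str | Path) -> None:
    """Write edges back out in the standard 12-column tabular layout.

    Floats are serialized with :func:`repr` so that a write/read cycle
    reproduces the edge list exactly.
    """
    with open(path, "w", encoding="utf-8") as handle:
        for e in edges:
            handle.write(
                "\t".join((
                    e.query_id, e.subject_id,
                    repr(e.percent_identity), str(e.alignment_length),
                    str(e.mismatches), str(e.gap_opens),
                    str(e.q_start), str(e.q_end), str(e.s_start), str(e.s_end),
                    repr(e.evalue), repr(e.bit_score),
                )) + "\n"
            )


# ---------------------------------------------------------------------------
# read-on-contig dialects

def _parse_soap(fields: list[str]) -> tuple[str, str, int]:
    if len(fields) < 3:
        raise ValueError(
            f"soap dialect expects >= 3 whitespace-separated fields, found {len(fields)}"
        )
    return fields[0], fields[1], _parse_int(fields[2], "position")


def _parse_tsv2col(fields: list[str]) -> tuple[str, str, int]:
    if len(fields) < 2:
        raise ValueError(
            f"tsv2col dialect expects 2 fields, found {len(fields)}"
        )
    return fields[0], fields[1], 0


#: Registered read-on-contig dialects.  Assembler intermediate formats vary
#: by version, so the registry is open: callers may add their own parser
#: taking the whitespace-split fields and returning (read, contig, position).
READ_MATCH_DIALECTS: dict[str, Callable[[list[str]], tuple[str, str, int]]] = {
    "soap": _parse_soap,
    "tsv2col": _parse_tsv2col,
}


def read_read_matches(path: str | Path, dialect: str = "soap") -> list[ReadMatchRecord]:
    """Parse read→contig match records, collapsing duplicate pairs.

    A read contributes at most once per contig: duplicate
    ``(read_id, contig_id)`` pairs are collapsed to the first occurrence.
    ``.gz`` paths are decompressed transparently.

    Raises
    ------
    KeyError
        Unknown dialect (the message lists the registered ones).
    BlastParseError
        Malformed line, naming the line number.
    """
    try:
        parse = READ_MATCH_DIALECTS[dialect]
    except KeyError:
        registered = ", ".join(sorted(READ_MATCH_DIALECTS))
        raise KeyError(
            f"unknown read-match dialect {dialect!r}; registered: {registered}"
        ) from None

    records: list[ReadMatchRecord] = []
    seen: set[tuple[str, str]] = set()
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                read_id, contig_id, position = parse(line.split())
                record = ReadMatchRecord(read_id, contig_id, position)
            except ValueError as exc:
                raise BlastParseError(path, lineno, str(exc)) from None
            key = (record.read_id, record.contig_id)
            if key in seen:
                continue
            seen.add(key)
            records.append(record)
    return records


def read_scaffold_members(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV mapping contig_id → scaffold_id.

    Raises :class:`BlastParseError` if a contig maps to two different
    scaffolds (the membership must be a function).
    """
    mapping: dict[str, str] = {}
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise BlastParseError(
                    path, lineno, "expected 2 tab-separated fields (contig, scaffold)"
                )
            contig, scaffold = fields[0], fields[1]
            if contig in mapping and mapping[contig] != scaffold:
                raise BlastParseError(
                    path, lineno,
                    f"contig {contig!r} mapped to both {mapping[contig]!r} and {scaffold!r}",
                )
            mapping[contig] = scaffold
    return mapping


# ---------------------------------------------------------------------------
# cluster result table

_CLUSTER_HEADER = (
    "cluster_id", "n_fragments", "fragments", "n_proteins", "proteins",
    "nearest_homolog", "nearest_evalue", "n_edges",
    "edge_len_min", "edge_len_max", "edge_len_mean", "read_count",
)


def write_cluster_table(records: Iterable["ClusterRecord"], path: str | Path) -> None:
    """Write annotated super-contig clusters as tab-delimited text.

    One row per cluster; member lists comma-joined in sorted order.  The
    table round-trips losslessly through :func:`read_cluster_table`.
    """
    from .annotation import ClusterRecord  # noqa: F401  (type only)

    with open(path, "w", encoding="utf-8") as handle:
        handle.write("#" + "\t".join(_CLUSTER_HEADER) + "\n")
        for r in records:
            handle.write(
                "\t".join((
                    str(r.cluster_id),
                    str(len(r.member_fragments)),
                    ",".join(sorted(r.member_fragments)),
                    str(len(r.member_proteins)),
                    ",".join(sorted(r.member_proteins)),
                    r.nearest_homolog,
                    repr(r.nearest_evalue),
                    str(r.n_edges),
                    repr(r.edge_len_min),
                    repr(r.edge_len_max),
                    repr(r.edge_len_mean),
                    str(r.read_count),
                )) + "\n"
            )


def read_cluster_table(path: str | Path) -> list["ClusterRecord"]:
    """Read a cluster table written by :func:`write_cluster_table`."""
    from .annotation import ClusterRecord

    records: list[ClusterRecord] = []
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(_CLUSTER_HEADER):
                raise BlastParseError(
                    path, lineno,
                    f"expected {len(_CLUSTER_HEADER)} fields, found {len(fields)}",
                )
            try:
                records.append(ClusterRecord(
                    cluster_id=int(fields[0]),
                    member_fragments=frozenset(
                        fields[2].split(",") if fields[2] else ()
                    ),
                    member_proteins=frozenset(
                        fields[4].split(",") if fields[4] else ()
                    ),
                    nearest_homolog=fields[5],
                    nearest_evalue=float(fields[6]),
                    n_edges=int(fields[7]),
                    edge_len_min=float(fields[8]),
                    edge_len_max=float(fields[9]),
                    edge_len_mean=float(fields[10]),
                    read_count=int(fields[11]),
                ))
            except ValueError as exc:
                raise BlastParseError(path, lineno, str(exc)) from None
    return records
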