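"""Parsing and aggregation of LCA assignment files.

The LCA file is tab-separated text, one read per line: a read-identifier
field followed by the taxonomic path of the read's assigned node, ordered
from the assigned node up to the root.  Each path entry encodes
``taxid:name:rank``.  Names may themselves contain colons, so entries are
split from both ends: taxid from the left, rank from the right, the middle
remainder is the name.  Taxids are always compared as strings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Sequence, TextIO, Tuple


class LcaParseError(ValueError):
    """A malformed LCA line; carries the 1-based line number."""

    def __init__(self, message: str, lineno: int | None = None):
        self.lineno = lineno
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class TaxNode:
    taxid: str
    name: str
    rank: str

    def __post_init__(self) -> None:
        if not self.taxid:
            raise ValueError("taxid must be non-empty")

    def entry(self) -> str:
        return f"{self.taxid}:{self.name}:{self.rank}"


# A taxonomic path: assigned node first, root last.
TaxPath = Tuple[TaxNode, ...]


@dataclass(frozen=True)
class LcaAssignment:
    read_id: str
    path: TaxPath
    raw_read_field: str = ""

    @property
    def taxid(self) -> str:
        return self.path[0].taxid

    def taxids(self) -> Tuple[str, ...]:
        return tuple(n.taxid for n in self.path)


# Trailing ":<digits>:<sequence>" metadata that some LCA producers append to
# the read-name field.  Pure numeric tokens alone are NOT stripped (Illumina
# read names end in numeric coordinate fields).
_META_SUFFIX = re.compile(r":\d+:[ACGTNacgtn]+$")


def strip_read_metadata(raw: str) -> str:
    """Heuristic removal of appended length/sequence metadata from a read
    field.  When a companion BAM is streamed the BAM read name is the
    authority (see :func:`read_field_matches`); this is for standalone use."""
    return _META_SUFFIX.sub("", raw)


def read_field_matches(raw: str, bam_read_name: str) -> bool:
    """True if an LCA read field refers to the given BAM read name."""
    return raw == bam_read_name or raw.startswith(bam_read_name + ":")


def parse_lca_entry(token: str, lineno: int | None = None) -> TaxNode:
    token = token.strip()
    left = token.find(":")
    right = token.rfind(":")
    if left < 0 or right <= left:
        raise LcaParseError(f"path entry not splittable into taxid:name:rank: {token!r}", lineno)
    taxid = token[:left].strip().strip('"')
    name = token[left + 1 : right].strip().strip('"')
    rank = token[right + 1 :].strip().strip('"')
    if not taxid:
        raise LcaParseError(f"empty taxid in path entry {token!r}", lineno)
    return TaxNode(taxid=taxid, name=name, rank=rank)


def parse_lca_line(line: str, lineno: int | None = None) -> LcaAssignment:
    """Parse one LCA record.

    Returns the read id stripped of any appended metadata suffix and the
    taxonomic path ordered assigned-node-first.  Raises
    :class:`LcaParseError` on empty lines or entries that cannot be split.
    """
    line = line.rstrip("\n")
    if not line.strip():
        raise LcaParseError("empty line", lineno)
    fields = line.split("\t")
    if len(fields) < 2:
        raise LcaParseError("no path entries", lineno)
    raw = fields[0]
    path = tuple(parse_lca_entry(tok, lineno) for tok in fields[1:] if tok.strip())
    if not path:
        raise LcaParseError("no path entries", lineno)
    return LcaAssignment(read_id=strip_read_metadata(raw), path=path, raw_read_field=raw)


def format_lca_line(assignment: LcaAssignment) -> str:
    raw = assignment.raw_read_field or assignment.read_id
    return "\t".join([raw] + [n.entry() for n in assignment.path])


def iter_lca_file(handle: TextIO | str) -> Iterator[Tuple[int, LcaAssignment]]:
    """Yield (lineno, assignment) for every record, skipping comment/header
    lines that start with '#'."""
    close = False
    if isinstance(handle, str):
        handle = open(handle)
        close = True
    try:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith("#") or not line.strip():
                continue
            yield lineno, parse_lca_line(line, lineno)
    finally:
        if close:
            handle.close()


def is_at_or_below_rank(path: Sequence[TaxNode], threshold_rank: str) -> bool:
    """True iff the assignment is at or below ``threshold_rank``: some node
    of the path (the assigned node or an ancestor) carries exactly that rank.
    No rank ladder is assumed; path membership is the test."""
    return any(node.rank == threshold_rank for node in path)


def aggregate_counts(assignments: Iterable[LcaAssignment]) -> Dict[str, int]:
    """Aggregated read counts: each read increments its assigned node and
    every ancestor on its path exactly once, so count(node) is the number of
    reads assigned to that node or any of its descendants."""
    counts: Dict[str, int] = {}
    for a in assignments:
        for taxid in a.taxids():
            counts[taxid] = counts.get(taxid, 0) + 1
    return counts
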