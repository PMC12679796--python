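"""Streaming of read-name-grouped BAMs synchronized with an LCA file.

A query-name-sorted (or at least read-name-grouped) BAM is consumed in lock
step with the LCA file, which drives the iteration: for every LCA line the
BAM is scanned forward to the matching read-name group.  Reference context
is rebuilt per alignment from query + CIGAR + MD, so no reference FASTA is
ever needed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple

import pysam

from .primitives import reverse_complement
from .taxonomy import LcaAssignment, read_field_matches

# CIGAR operation codes (htslib numbering)
_CMATCH, _CINS, _CDEL, _CREF_SKIP, _CSOFT_CLIP, _CHARD_CLIP, _CPAD, _CEQUAL, _CDIFF = range(9)
_QUERY_OPS = {_CMATCH, _CINS, _CSOFT_CLIP, _CEQUAL, _CDIFF}
_REF_OPS = {_CMATCH, _CDEL, _CREF_SKIP, _CEQUAL, _CDIFF}
_ALIGN_OPS = {_CMATCH, _CEQUAL, _CDIFF}

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


class MdError(ValueError):
    """MD tag inconsistent with the CIGAR string."""


class DesyncError(RuntimeError):
    """BAM and LCA streams can no longer be aligned by forward scanning."""

    def __init__(self, lca_read: str, bam_read: Optional[str]):
        self.lca_read = lca_read
        self.bam_read = bam_read
        super().__init__(
            f"BAM/LCA desynchronization: LCA read {lca_read!r} not reachable by "
            f"forward scan (BAM at {bam_read!r})"
        )


@dataclass
class AlignmentRecord:
    """One alignment line, decoupled from pysam for pure computation."""

    read_id: str
    reference_name: str
    is_reverse: bool
    query_sequence: str  # as stored (reference-forward orientation)
    cigar: Tuple[Tuple[int, int], ...]  # (op, length) htslib codes
    md: Optional[str]
    alignment_score: Optional[int]
    edit_distance: Optional[int]

    @classmethod
    def from_pysam(cls, aln: "pysam.AlignedSegment") -> "AlignmentRecord":
        def tag(name: str):
            try:
                return aln.get_tag(name)
            except KeyError:
                return None

        return cls(
            read_id=aln.query_name,
            reference_name=aln.reference_name or "",
            is_reverse=aln.is_reverse,
            query_sequence=aln.query_sequence or "",
            cigar=tuple(aln.cigartuples or ()),
            md=tag("MD"),
            alignment_score=tag("AS"),
            edit_distance=tag("NM"),
        )


@dataclass
class AlignedColumns:
    """Per-column decomposition of one alignment.

    ``columns`` holds (query_position, ref_base, read_base) for every
    M/=/X column, in reference order; ``reference`` is the full aligned
    reference segment (match columns plus deleted bases).
    """

    columns: List[Tuple[int, str, str]]
    reference: str
    matched: int
    mismatched: int

    @property
    def aligned(self) -> int:
        return self.matched + self.mismatched


def _md_tokens(md: str) -> Iterator[Tuple[str, str]]:
    pos = 0
    for m in _MD_TOKEN.finditer(md):
        if m.start() != pos:
            raise MdError(f"unparseable MD tag {md!r}")
        pos = m.end()
        if m.group(1) is not None:
            yield ("match", m.group(1))
        elif m.group(2) is not None:
            yield ("del", m.group(2)[1:])
        else:
            yield ("mismatch", m.group(3))
    if pos != len(md):
        raise MdError(f"unparseable MD tag {md!r}")


def aligned_columns(record: AlignmentRecord) -> AlignedColumns:
    """Rebuild reference bases from query + CIGAR + MD.

    Raises :class:`MdError` when the MD tag does not cover exactly the
    alignment's match and deletion columns.
    """
    if record.md is None:
        raise MdError("missing MD tag")
    query = record.query_sequence.upper()
    # slots: one per reference-consuming column, in reference order.
    # match columns carry their query position; deletions carry None.
    slots: List[Optional[int]] = []
    qpos = 0
    for op, length in record.cigar:
        if op in _ALIGN_OPS:
            slots.extend(range(qpos, qpos + length))
            qpos += length
        elif op in (_CINS, _CSOFT_CLIP):
            qpos += length
        elif op in (_CDEL, _CREF_SKIP):
            slots.extend([None] * length)
        # hard clips and pads consume nothing here
    if qpos != len(query) and query:
        raise MdError("CIGAR does not consume the stored query length")

    ref_chars: List[str] = []
    columns: List[Tuple[int, str, str]] = []
    matched = 0
    mismatched = 0
    i = 0
    for kind, value in _md_tokens(record.md):
        if kind == "match":
            n = int(value)
            for _ in range(n):
                if i >= len(slots) or slots[i] is None:
                    raise MdError("MD match run overruns alignment columns")
                q = slots[i]
                base = query[q]
                ref_chars.append(base)
                columns.append((q, base, base))
                matched += 1
                i += 1
        elif kind == "mismatch":
            if i >= len(slots) or slots[i] is None:
                raise MdError("MD mismatch does not land on a match column")
            q = slots[i]
            ref_base = value.upper()
            ref_chars.append(ref_base)
            columns.append((q, ref_base, query[q]))
            mismatched += 1
            i += 1
        else:  # deletion
            for ref_base in value.upper():
                if i >= len(slots) or slots[i] is not None:
                    raise MdError("MD deletion does not land on a deletion column")
                ref_chars.append(ref_base)
                i += 1
    if i != len(slots):
        raise MdError("MD tag does not cover all reference columns")
    return AlignedColumns(
        columns=columns, reference="".join(ref_chars), matched=matched, mismatched=mismatched
    )


def reconstruct_reference_segment(record: AlignmentRecord) -> str:
    """The reference bases spanned by the alignment (matches + deletions)."""
    return aligned_columns(record).reference


def alignment_similarity(record: AlignmentRecord, query_len: Optional[int] = None) -> float:
    """Matched columns divided by the full read length (soft clips stay in
    the denominator)."""
    cols = aligned_columns(record)
    if query_len is None:
        query_len = len(record.query_sequence)
    if query_len <= 0:
        return 0.0
    return cols.matched / query_len


@dataclass
class OrientedMismatchProfile:
    """Reference/read base pairs in sequenced-molecule orientation.

    Each pair is (offset5, offset3, ref_base, read_base) with 1-based offsets
    from the molecule's 5' and 3' ends.  Reverse-strand alignments are
    complement-flipped first, so "5'" always refers to the sequenced
    molecule.  Insertions, deletions and non-ACGT pairs are skipped.
    """

    pairs: List[Tuple[int, int, str, str]]
    matched: int
    aligned: int
    read_len: int


_ACGT = frozenset("ACGT")


def oriented_substitutions(record: AlignmentRecord, max_offset: Optional[int] = None) -> OrientedMismatchProfile:
    """Per-column (ref, read) pairs with terminal offsets, read-oriented.

    ``max_offset`` limits pairs to those within that many bases of either
    end; None keeps every aligned column (needed for PMD scoring).
    """
    cols = aligned_columns(record)
    L = len(record.query_sequence)
    pairs: List[Tuple[int, int, str, str]] = []
    comp = str.maketrans("ACGT", "TGCA")
    for qpos, ref_base, read_base in cols.columns:
        if ref_base not in _ACGT or read_base not in _ACGT:
            continue
        if record.is_reverse:
            pos = L - 1 - qpos
            ref_base = ref_base.translate(comp)
            read_base = read_base.translate(comp)
        else:
            pos = qpos
        off5 = pos + 1
        off3 = L - pos
        if max_offset is not None and off5 > max_offset and off3 > max_offset:
            continue
        pairs.append((off5, off3, ref_base, read_base))
    return OrientedMismatchProfile(
        pairs=pairs, matched=cols.matched, aligned=cols.aligned, read_len=L
    )


@dataclass
class ReadBundle:
    """One read's full alignment group plus its LCA assignment."""

    read_id: str
    alignments: List[AlignmentRecord]
    lca: LcaAssignment

    @property
    def query_len(self) -> int:
        return max(len(a.query_sequence) for a in self.alignments)

    def read_sequence(self) -> str:
        """The read in sequencing (molecule) orientation."""
        for a in self.alignments:
            if not a.is_reverse:
                return a.query_sequence
        return reverse_complement(self.alignments[0].query_sequence)


def _iter_bam_groups(bam: "pysam.AlignmentFile") -> Iterator[Tuple[str, List[pysam.AlignedSegment]]]:
    name = None
    group: List[pysam.AlignedSegment] = []
    for aln in bam:
        if aln.query_name != name:
            if group:
                yield name, group
            name = aln.query_name
            group = []
        group.append(aln)
    if group:
        yield name, group


def read_bundles(
    bam: "pysam.AlignmentFile",
    lca_assignments: Iterable[LcaAssignment],
    keep_pysam: bool = False,
) -> Iterator[ReadBundle]:
    """Synchronized iteration: one bundle per LCA line with mapped alignments.

    The LCA stream drives; BAM groups not named by any LCA line are skipped.
    Raises :class:`DesyncError` when the current LCA read cannot be reached
    by scanning the BAM forward (out-of-order or missing read).  Memory is
    bounded: at most one read group is held at a time.
    """
    groups = _iter_bam_groups(bam)
    last_name: Optional[str] = None
    for lca in lca_assignments:
        found = None
        for name, group in groups:
            last_name = name
            if read_field_matches(lca.raw_read_field or lca.read_id, name):
                found = (name, group)
                break
        if found is None:
            raise DesyncError(lca.raw_read_field or lca.read_id, last_name)
        name, group = found
        mapped = [a for a in group if not a.is_unmapped]
        if not mapped:
            continue
        records = [AlignmentRecord.from_pysam(a) for a in mapped]
        bundle = ReadBundle(read_id=name, alignments=records, lca=lca)
        if keep_pysam:
            bundle.pysam_alignments = mapped  # type: ignore[attr-defined]
        yield bundle


def best_alignment_index(records: Sequence[AlignmentRecord], rng) -> int:
    """Index of the AS-best alignment; ties broken by the supplied RNG.
    Records without an AS tag score as minus infinity."""
    scores = [r.alignment_score if r.alignment_score is not None else float("-inf") for r in records]
    best = max(scores)
    candidates = [i for i, s in enumerate(scores) if s == best]
    if len(candidates) == 1:
        return candidates[0]
    return candidates[rng.randrange(len(candidates))]
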