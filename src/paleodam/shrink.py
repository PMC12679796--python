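"""Two-pass shrinking of a BAM + LCA pair.

Pass 1 scans the LCA file alone, drops reads whose path touches an excluded
taxid, aggregates the remaining reads up the taxonomy, and selects the
taxonomic nodes that are at or below the rank threshold with enough
aggregated support.  Pass 2 re-streams both files and writes out only the
reads assigned to kept nodes, keeping only alignments of sufficient
similarity.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Set, TextIO, Tuple

import pysam

from . import taxonomy
from .alignment import (
    AlignmentRecord,
    MdError,
    alignment_similarity,
    oriented_substitutions,
    read_bundles,
)
from .primitives import PmdParams, dust_score, pmd_score
from .taxonomy import LcaAssignment, format_lca_line, iter_lca_file

logger = logging.getLogger(__name__)

#: marker written as the first line of a shrunken LCA file so downstream
#: stages can verify provenance
SHRUNKEN_MARKER = "#paleodam:shrunken"

#: SAM auxiliary tag used for optional PMD annotation (lowercase = local use)
PMD_TAG = "pd"


@dataclass
class ShrinkConfig:
    rank_threshold: str = "family"
    min_reads: int = 5
    min_similarity: float = 0.9
    exclude_taxids: Set[str] = field(default_factory=set)
    max_dust: Optional[float] = None
    annotate_pmd: bool = False
    pmd_params: PmdParams = field(default_factory=PmdParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_similarity <= 1.0:
            raise ValueError("min_similarity must be in [0, 1]")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        self.exclude_taxids = set(self.exclude_taxids)


@dataclass
class ShrinkReport:
    reads_in: int = 0
    reads_excluded: int = 0
    reads_out: int = 0
    reads_dropped_dust: int = 0
    reads_dropped_no_alignment: int = 0
    alignments_in: int = 0
    alignments_out: int = 0

    def as_dict(self) -> Dict[str, int]:
        return dict(self.__dict__)


def _excluded(assignment: LcaAssignment, exclude: Set[str]) -> bool:
    return bool(exclude) and any(t in exclude for t in assignment.taxids())


def select_kept_nodes(lca_path: str, cfg: ShrinkConfig) -> Set[str]:
    """Pass 1: the set of taxids that survive rank and support filtering.

    Reads whose path intersects ``cfg.exclude_taxids`` are dropped before
    counting; the rest still aggregate all the way up the taxonomy.  A node
    is kept when the rank threshold occurs at or above it in some path and
    its aggregated count reaches ``cfg.min_reads``.
    """
    counts: Dict[str, int] = {}
    eligible: Set[str] = set()
    for _, assignment in iter_lca_file(lca_path):
        if _excluded(assignment, cfg.exclude_taxids):
            continue
        path = assignment.path
        threshold_idx = None
        for i, node in enumerate(path):
            if node.rank == cfg.rank_threshold:
                threshold_idx = i
                break
        for i, node in enumerate(path):
            counts[node.taxid] = counts.get(node.taxid, 0) + 1
            if threshold_idx is not None and i <= threshold_idx:
                eligible.add(node.taxid)
    return {t for t in eligible if counts.get(t, 0) >= cfg.min_reads}


def write_shrunken_outputs(
    bam_path: str,
    lca_path: str,
    out_bam_path: str,
    out_lca_path: str,
    kept: Set[str],
    cfg: ShrinkConfig,
) -> ShrinkReport:
    """Pass 2: write the shrunken LCA and BAM.

    The output LCA holds exactly the (non-excluded) reads whose assigned
    node is kept, in input order; the output BAM holds, for those reads,
    exactly the alignments with similarity >= ``cfg.min_similarity``
    (inclusive).  Reads failing the optional DUST ceiling, or whose
    alignments all fail similarity, are dropped from both outputs.
    """
    report = ShrinkReport()
    rng = random.Random(cfg.seed)
    with pysam.AlignmentFile(bam_path, "rb", check_sq=False) as bam:
        header = bam.header
        with pysam.AlignmentFile(out_bam_path, "wb", header=header) as out_bam, open(
            out_lca_path, "w"
        ) as out_lca:
            out_lca.write(
                f"{SHRUNKEN_MARKER} upto={cfg.rank_threshold} mincount={cfg.min_reads} "
                f"minsim={cfg.min_similarity}\n"
            )

            def assignments():
                for _, a in iter_lca_file(lca_path):
                    report.reads_in += 1
                    if _excluded(a, cfg.exclude_taxids):
                        report.reads_excluded += 1
                        continue
                    if a.taxid in kept:
                        yield a

            for bundle in read_bundles(bam, assignments(), keep_pysam=True):
                report.alignments_in += len(bundle.alignments)
                if cfg.max_dust is not None:
                    if dust_score(bundle.read_sequence()) > cfg.max_dust:
                        report.reads_dropped_dust += 1
                        continue
                keep_idx = []
                for i, rec in enumerate(bundle.alignments):
                    try:
                        sim = alignment_similarity(rec, bundle.query_len)
                    except MdError:
                        logger.warning("skipping alignment without usable MD: %s", rec.read_id)
                        continue
                    if sim >= cfg.min_similarity:
                        keep_idx.append(i)
                if not keep_idx:
                    report.reads_dropped_no_alignment += 1
                    logger.info("read %s dropped: no alignment passes similarity", bundle.read_id)
                    continue
                out_lca.write(format_lca_line(bundle.lca) + "\n")
                report.reads_out += 1
                pysam_alns = bundle.pysam_alignments  # type: ignore[attr-defined]
                for i in keep_idx:
                    aln = pysam_alns[i]
                    if cfg.annotate_pmd:
                        profile = oriented_substitutions(bundle.alignments[i])
                        score = pmd_score(profile.pairs, cfg.pmd_params)
                        aln.set_tag(PMD_TAG, float(score), value_type="f")
                    out_bam.write(aln)
                    report.alignments_out += 1
    return report


def shrink(
    bam_path: str,
    lca_path: str,
    out_bam_path: str,
    out_lca_path: str,
    cfg: Optional[ShrinkConfig] = None,
) -> ShrinkReport:
    """Run both passes; the standard entry point."""
    cfg = cfg or ShrinkConfig()
    kept = select_kept_nodes(lca_path, cfg)
    return write_shrunken_outputs(bam_path, lca_path, out_bam_path, out_lca_path, kept, cfg)


def is_shrunken_lca(lca_path: str) -> bool:
    """True when the LCA file carries the shrink provenance marker."""
    with open(lca_path) as fh:
        first = fh.readline()
    return first.startswith(SHRUNKEN_MARKER)
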