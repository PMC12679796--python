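"""Single-pass per-node authentication statistics.

One streaming pass over a shrunken BAM + LCA pair fills a ``NodeStats``
accumulator for the assigned node of every read and all of its ancestors.
Per-read quantities (counts, DUST, length, read GC, k-mers) are added once
per read regardless of mode; per-alignment quantities (substitutions, ANI,
reference GC) are added under one of three weighting modes:

* mode 1 - weight 1 on the AS-best alignment (seeded random tie-break)
* mode 2 - weight 1/m on each of the read's m alignments
* mode 3 - weight 1 on every alignment
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pysam

from .alignment import (
    AlignmentRecord,
    MdError,
    OrientedMismatchProfile,
    ReadBundle,
    best_alignment_index,
    oriented_substitutions,
    read_bundles,
)
from .primitives import HyperLogLog, canonical_kmer_stream, dust_score, gc_fraction, kmer_hash
from .taxonomy import TaxNode, iter_lca_file

logger = logging.getLogger(__name__)

ENDS = ("5p", "3p")
NA = "NA"


@dataclass
class ComputeConfig:
    mode: int = 1
    stranded: str = "ds"  # "ds" or "ss"; no silent default in the CLI
    k: int = 29
    max_offset: int = 15  # terminal offsets tracked per read end
    hll_precision: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in (1, 2, 3):
            raise ValueError("mode must be 1, 2 or 3")
        if self.stranded not in ("ds", "ss"):
            raise ValueError("stranded must be 'ds' or 'ss'")


class SubsTable:
    """Per-node substitution counts by read end, terminal offset and base
    pair.  Counts are integral under mode 1 and fractional otherwise."""

    __slots__ = ("counts",)

    def __init__(self) -> None:
        self.counts: Dict[Tuple[str, int, str, str], float] = {}

    def add(self, end: str, offset: int, ref: str, read: str, weight: float) -> None:
        key = (end, offset, ref, read)
        self.counts[key] = self.counts.get(key, 0.0) + weight

    def get(self, end: str, offset: int, ref: str, read: str) -> float:
        return self.counts.get((end, offset, ref, read), 0.0)

    def frequency(self, end: str, offset: int, ref: str, read: str) -> Optional[float]:
        """Substitution frequency conditional on the reference base; None
        when the reference base never occurs at that offset."""
        denom = sum(
            v for (e, o, r, _b), v in self.counts.items() if e == end and o == offset and r == ref
        )
        if denom <= 0:
            return None
        return self.get(end, offset, ref, read) / denom


@dataclass
class NodeStats:
    node: TaxNode
    path_entries: str = ""
    total_reads: int = 0
    unaggregated_reads: int = 0
    total_kmers: int = 0
    sketch: HyperLogLog = None  # type: ignore[assignment]
    exact_kmers: Optional[set] = None  # only kept when cfg asks for it (tests)
    dust_sum: float = 0.0
    length_sum: float = 0.0
    read_gc_sum: float = 0.0
    ani_weighted_sum: float = 0.0
    ref_gc_weighted_sum: float = 0.0
    weight_sum: float = 0.0
    subs: SubsTable = field(default_factory=SubsTable)


@dataclass
class StatsRow:
    name: str
    taxid: str
    total_reads: int
    duplicity: Optional[float]
    mean_dust: Optional[float]
    damage5: Optional[float]
    damage3: Optional[float]
    mean_length: Optional[float]
    ani: Optional[float]
    mean_read_gc: Optional[float]
    mean_ref_gc: Optional[float]
    unique_kmers: Optional[float]
    unaggregated_reads: int
    tax_path: str


COLUMNS = [
    "name",
    "taxid",
    "total_reads",
    "duplicity",
    "mean_dust",
    "damage5",
    "damage3",
    "mean_length",
    "ani",
    "mean_read_gc",
    "mean_ref_gc",
    "unique_kmers",
    "unaggregated_reads",
    "tax_path",
]


def _fmt(value, integral: bool = False) -> str:
    if value is None:
        return NA
    if integral:
        return str(int(value))
    return f"{value:.6g}"


def _mode_weights(bundle: ReadBundle, mode: int, rng: random.Random) -> List[float]:
    m = len(bundle.alignments)
    if mode == 1:
        weights = [0.0] * m
        weights[best_alignment_index(bundle.alignments, rng)] = 1.0
        return weights
    if mode == 2:
        return [1.0 / m] * m
    return [1.0] * m


def accumulate_bundle(
    stats: Dict[str, NodeStats],
    bundle: ReadBundle,
    cfg: ComputeConfig,
    rng: random.Random,
    track_exact_kmers: bool = False,
) -> None:
    """Fold one read's bundle into the per-node accumulators.

    Per-read quantities go once to the assigned node and every ancestor;
    per-alignment quantities go to the same nodes with mode weights.
    """
    path = bundle.lca.path
    nodes: List[NodeStats] = []
    for tax_node in path:
        ns = stats.get(tax_node.taxid)
        if ns is None:
            ns = NodeStats(node=tax_node, sketch=HyperLogLog(p=cfg.hll_precision))
            if track_exact_kmers:
                ns.exact_kmers = set()
            ns.path_entries = ";".join(n.entry() for n in path[path.index(tax_node):])
        stats[tax_node.taxid] = ns
        nodes.append(ns)

    seq = bundle.read_sequence()
    dust = dust_score(seq)
    gc = gc_fraction(seq)
    kmers = list(canonical_kmer_stream(seq, cfg.k))
    hashes = [kmer_hash(km) for km in kmers]
    for ns in nodes:
        ns.total_reads += 1
        ns.dust_sum += dust
        ns.length_sum += len(seq)
        ns.read_gc_sum += gc
        ns.total_kmers += len(kmers)
        ns.sketch.add_hashes(hashes)
        if ns.exact_kmers is not None:
            ns.exact_kmers.update(kmers)
    nodes[0].unaggregated_reads += 1

    weights = _mode_weights(bundle, cfg.mode, rng)
    for rec, w in zip(bundle.alignments, weights):
        if w == 0.0:
            continue
        try:
            profile = oriented_substitutions(rec)
        except MdError as exc:
            logger.warning("alignment of %s skipped: %s", rec.read_id, exc)
            continue
        ani = profile.matched / profile.aligned if profile.aligned else 0.0
        ref_gc = _profile_ref_gc(profile)
        for ns in nodes:
            ns.ani_weighted_sum += w * ani
            ns.ref_gc_weighted_sum += w * ref_gc
            ns.weight_sum += w
            for off5, off3, ref, read in profile.pairs:
                if off5 <= cfg.max_offset:
                    ns.subs.add("5p", off5, ref, read, w)
                if off3 <= cfg.max_offset:
                    ns.subs.add("3p", off3, ref, read, w)


def _profile_ref_gc(profile: OrientedMismatchProfile) -> float:
    gc = at = 0
    for _o5, _o3, ref, _read in profile.pairs:
        if ref in ("G", "C"):
            gc += 1
        else:
            at += 1
    total = gc + at
    return gc / total if total else 0.0


def finalize_stats_table(stats: Dict[str, NodeStats], cfg: ComputeConfig) -> List[StatsRow]:
    """Turn accumulators into ordered output rows.

    duplicity = total k-mers / HLL unique estimate (0 when no k-mers were
    seen); damage5 is the 5' offset-1 C->T frequency; damage3 is the 3'
    offset-1 C->T (ss) or G->A (ds) frequency; weighted means divide by the
    mode weight sum.  Rows are ordered by total reads descending, ties by
    taxid ascending.  Zero denominators yield None (written as NA).
    """
    rows: List[StatsRow] = []
    for ns in stats.values():
        unique = ns.sketch.estimate()
        if ns.total_kmers == 0:
            duplicity = 0.0
            unique_out: Optional[float] = 0.0
        else:
            unique_out = unique
            duplicity = ns.total_kmers / unique if unique > 0 else None
        n = ns.total_reads
        damage5 = ns.subs.frequency("5p", 1, "C", "T")
        if cfg.stranded == "ss":
            damage3 = ns.subs.frequency("3p", 1, "C", "T")
        else:
            damage3 = ns.subs.frequency("3p", 1, "G", "A")
        w = ns.weight_sum
        rows.append(
            StatsRow(
                name=ns.node.name,
                taxid=ns.node.taxid,
                total_reads=n,
                duplicity=duplicity,
                mean_dust=ns.dust_sum / n if n else None,
                damage5=damage5,
                damage3=damage3,
                mean_length=ns.length_sum / n if n else None,
                ani=ns.ani_weighted_sum / w if w > 0 else None,
                mean_read_gc=ns.read_gc_sum / n if n else None,
                mean_ref_gc=ns.ref_gc_weighted_sum / w if w > 0 else None,
                unique_kmers=unique_out,
                unaggregated_reads=ns.unaggregated_reads,
                tax_path=ns.path_entries,
            )
        )
    rows.sort(key=lambda r: (-r.total_reads, r.taxid))
    return rows


def write_stats_table(rows: Sequence[StatsRow], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.name,
                        r.taxid,
                        str(r.total_reads),
                        _fmt(r.duplicity),
                        _fmt(r.mean_dust),
                        _fmt(r.damage5),
                        _fmt(r.damage3),
                        _fmt(r.mean_length),
                        _fmt(r.ani),
                        _fmt(r.mean_read_gc),
                        _fmt(r.mean_ref_gc),
                        _fmt(r.unique_kmers),
                        str(r.unaggregated_reads),
                        r.tax_path,
                    ]
                )
                + "\n"
            )


def write_subs_file(stats: Dict[str, NodeStats], path: str, order: Optional[Sequence[str]] = None) -> None:
    """One record per node: taxid, name, then every nonzero substitution
    count as ``end:offset:REFREAD:count`` tokens in deterministic order.
    Counts use 6 significant digits, so write -> read -> write is stable."""
    if order is None:
        ordered = sorted(stats.values(), key=lambda ns: (-ns.total_reads, ns.node.taxid))
    else:
        ordered = [stats[t] for t in order if t in stats]
    with open(path, "w") as fh:
        for ns in ordered:
            tokens = []
            for (end, offset, ref, read), v in sorted(ns.subs.counts.items()):
                if v != 0.0:
                    tokens.append(f"{end}:{offset}:{ref}{read}:{v:.6g}")
            fh.write("\t".join([ns.node.taxid, ns.node.name] + tokens) + "\n")


def read_subs_file(path: str) -> Dict[str, Tuple[str, SubsTable]]:
    """Inverse of :func:`write_subs_file`: taxid -> (name, SubsTable)."""
    out: Dict[str, Tuple[str, SubsTable]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            taxid, name = fields[0], fields[1]
            table = SubsTable()
            for token in fields[2:]:
                end, offset, pair, count = token.split(":")
                table.add(end, int(offset), pair[0], pair[1], float(count))
            out[taxid] = (name, table)
    return out


def compute(
    bam_path: str,
    lca_path: str,
    out_tsv: str,
    out_subs: str,
    cfg: ComputeConfig,
) -> List[StatsRow]:
    """Full compute stage: stream, accumulate, finalize, write both files."""
    stats: Dict[str, NodeStats] = {}
    rng = random.Random(cfg.seed)
    n_reads = 0
    with pysam.AlignmentFile(bam_path, "rb", check_sq=False) as bam:
        assignments = (a for _, a in iter_lca_file(lca_path))
        for bundle in read_bundles(bam, assignments):
            accumulate_bundle(stats, bundle, cfg, rng)
            n_reads += 1
    rows = finalize_stats_table(stats, cfg)
    write_stats_table(rows, out_tsv)
    write_subs_file(stats, out_subs, order=[r.taxid for r in rows])
    logger.info("compute: %d reads, %d taxonomic nodes", n_reads, len(rows))
    return rows
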