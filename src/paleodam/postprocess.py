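"""Downstream artifacts: multi-sample combination, taxon extraction,
Krona XML emission, and plotting.

Plot functions return the plotted series so tests can assert on values
rather than on rendered pixels; figures are written with the Agg backend.
"""

from __future__ import annotations

import logging
import random
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
import pysam

from .alignment import best_alignment_index, AlignmentRecord, read_bundles
from .compute import NA, SubsTable, read_subs_file
from .taxonomy import iter_lca_file

logger = logging.getLogger(__name__)

DEFAULT_METRICS = (
    "duplicity",
    "mean_dust",
    "damage5",
    "damage3",
    "mean_length",
    "ani",
    "mean_read_gc",
    "mean_ref_gc",
)


def load_stats_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"taxid": str}, na_values=[NA], keep_default_na=False)
    if df["taxid"].duplicated().any():
        raise ValueError(f"duplicate taxids in stats table {path}")
    return df


def combine_tables(
    tables: Dict[str, pd.DataFrame],
    metrics: Sequence[str] = DEFAULT_METRICS,
) -> pd.DataFrame:
    """Merge per-sample stats tables into one abundance matrix.

    Rows are the union of taxa.  Read counts become ``reads_<sample>``
    columns (0 where absent); each selected metric gains per-sample columns
    and a read-weighted mean over the samples where it is non-NA.
    """
    if not tables:
        raise ValueError("no input tables")
    ids = list(tables)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")

    base = None
    for sid, df in tables.items():
        cols = df[["taxid", "name", "tax_path"]]
        base = cols if base is None else pd.concat([base, cols]).drop_duplicates("taxid")
    out = base.reset_index(drop=True)

    for sid, df in tables.items():
        reads = df.set_index("taxid")["total_reads"]
        out[f"reads_{sid}"] = out["taxid"].map(reads).fillna(0).astype(int)
    read_cols = [f"reads_{sid}" for sid in ids]

    for metric in metrics:
        per_sample = []
        for sid, df in tables.items():
            col = out["taxid"].map(df.set_index("taxid")[metric])
            out[f"{metric}_{sid}"] = col
            per_sample.append(col)
        num = pd.Series(0.0, index=out.index)
        den = pd.Series(0.0, index=out.index)
        for sid, col in zip(ids, per_sample):
            w = out[f"reads_{sid}"].where(col.notna(), 0)
            num += col.fillna(0) * w
            den += w
        out[f"{metric}_wmean"] = num.where(den > 0) / den.where(den > 0)

    out["total_reads"] = out[read_cols].sum(axis=1)
    out = out.sort_values(["total_reads", "taxid"], ascending=[False, True]).drop(
        columns="total_reads"
    )
    return out.reset_index(drop=True)


def combine_files(paths: Dict[str, str], out_path: str, metrics: Sequence[str] = DEFAULT_METRICS) -> pd.DataFrame:
    tables = {sid: load_stats_table(p) for sid, p in paths.items()}
    combined = combine_tables(tables, metrics)
    combined.to_csv(out_path, sep="\t", index=False, na_rep=NA)
    return combined


def extract_taxa_bam(
    bam_path: str,
    lca_path: str,
    taxids: Set[str],
    out_bam_path: str,
    best_only: bool = False,
    top_reference_only: bool = False,
    seed: int = 0,
) -> int:
    """Write alignments of reads assigned at or below any of ``taxids``.

    The output header is subset to exactly the references appearing in the
    retained alignments.  ``best_only`` keeps one AS-best alignment per read
    (seeded tie-break); ``top_reference_only`` keeps alignments to the single
    reference hit by the most distinct qualifying reads (ties by name).
    Returns the number of alignments written.
    """
    taxids = set(taxids)

    def qualifying_bundles(bam):
        assignments = (
            a for _, a in iter_lca_file(lca_path) if any(t in taxids for t in a.taxids())
        )
        yield from read_bundles(bam, assignments, keep_pysam=True)

    # pass 1: decide retained alignments per read; collect reference usage
    rng = random.Random(seed)
    ref_support: Dict[str, Set[str]] = {}
    chosen: Dict[str, List[int]] = {}
    with pysam.AlignmentFile(bam_path, "rb", check_sq=False) as bam:
        for bundle in qualifying_bundles(bam):
            if best_only:
                idx = [best_alignment_index(bundle.alignments, rng)]
            else:
                idx = list(range(len(bundle.alignments)))
            chosen[bundle.read_id] = idx
            for i in idx:
                ref = bundle.alignments[i].reference_name
                ref_support.setdefault(ref, set()).add(bundle.read_id)

    if not chosen:
        logger.warning("extract: no reads assigned at or below %s", sorted(taxids))

    top_ref = None
    if top_reference_only and ref_support:
        top_ref = min(ref_support, key=lambda r: (-len(ref_support[r]), r))

    # pass 2: determine which references actually appear in the output
    used_refs: Set[str] = set()
    with pysam.AlignmentFile(bam_path, "rb", check_sq=False) as bam:
        for bundle in qualifying_bundles(bam):
            for i in chosen.get(bundle.read_id, ()):
                ref = bundle.alignments[i].reference_name
                if top_ref is None or ref == top_ref:
                    used_refs.add(ref)

    with pysam.AlignmentFile(bam_path, "rb", check_sq=False) as bam:
        old_header = bam.header.to_dict()
        kept_sq = [sq for sq in old_header.get("SQ", []) if sq["SN"] in used_refs]
        new_header = dict(old_header)
        new_header["SQ"] = kept_sq
        tid = {sq["SN"]: i for i, sq in enumerate(kept_sq)}
        written = 0
        with pysam.AlignmentFile(out_bam_path, "wb", header=new_header) as out:
            for bundle in qualifying_bundles(bam):
                alns = bundle.pysam_alignments  # type: ignore[attr-defined]
                for i in chosen.get(bundle.read_id, ()):
                    ref = bundle.alignments[i].reference_name
                    if top_ref is not None and ref != top_ref:
                        continue
                    src = alns[i]
                    a = pysam.AlignedSegment(out.header)
                    a.query_name = src.query_name
                    a.query_sequence = src.query_sequence
                    a.flag = src.flag
                    a.reference_id = tid[ref]
                    a.reference_start = src.reference_start
                    a.mapping_quality = src.mapping_quality
                    a.cigartuples = src.cigartuples
                    a.query_qualities = src.query_qualities
                    for tag, value in src.get_tags():
                        a.set_tag(tag, value)
                    out.write(a)
                    written += 1
    return written


KRONA_ATTRIBUTES = [
    ("reads", "Reads"),
    ("damage", "5' C-to-T frequency"),
    ("duplicity", "K-mer duplicity"),
    ("dust", "Mean DUST score"),
    ("length", "Mean read length"),
]


def _krona_tree(tables: Dict[str, pd.DataFrame]):
    """Node dict tree keyed by path-from-root entries."""

    def new_node(entry: str):
        return {"entry": entry, "children": {}, "values": {}}

    root = new_node("1:root:no rank")
    for s_idx, (sid, df) in enumerate(tables.items()):
        for _, row in df.iterrows():
            entries = row["tax_path"].split(";")
            rev = list(reversed(entries))  # root ... assigned
            node = root
            if rev and rev[0].split(":", 1)[0] == root["entry"].split(":", 1)[0]:
                start = 1
                if root["entry"] == "1:root:no rank":
                    root["entry"] = rev[0]
            else:
                start = 0
            for entry in rev[start:]:
                taxid = entry.split(":", 1)[0]
                node = node["children"].setdefault(taxid, new_node(entry))
            node["values"][sid] = row
    return root


def krona_xml(
    tables: Dict[str, pd.DataFrame],
    out_path: str,
) -> ET.ElementTree:
    """Emit one multi-sample Krona XML document (ktImportXML dialect).

    Node magnitudes are total reads; per-node attributes carry damage5,
    duplicity, mean DUST, and mean length, one value per dataset.  A color
    directive binds wedge colour to the damage attribute; NA damage is
    rendered as 0 (flagged via the ``damage_na`` attribute).  Raises on
    parent/child read-count inversions.
    """
    sample_ids = list(tables)
    root_node = _krona_tree(tables)

    krona = ET.Element("krona")
    attrs = ET.SubElement(krona, "attributes", {"magnitude": "reads"})
    for name, display in KRONA_ATTRIBUTES:
        ET.SubElement(attrs, "attribute", {"display": display}).text = name
    ET.SubElement(attrs, "attribute", {"display": "Damage is NA"}).text = "damage_na"
    ET.SubElement(
        krona,
        "color",
        {
            "attribute": "damage",
            "valueStart": "0",
            "valueEnd": "0.3",
            "hueStart": "240",
            "hueEnd": "0",
            "default": "false",
        },
    )
    datasets = ET.SubElement(krona, "datasets")
    for sid in sample_ids:
        ET.SubElement(datasets, "dataset").text = sid

    def emit(node, parent_el, parent_reads: Optional[Dict[str, int]]):
        entry = node["entry"]
        taxid, rest = entry.split(":", 1)
        name = rest.rsplit(":", 1)[0]
        el = ET.SubElement(parent_el, "node", {"name": name})
        reads = {}
        per_attr: Dict[str, List[str]] = {a: [] for a, _ in KRONA_ATTRIBUTES}
        per_attr["damage_na"] = []
        for sid in sample_ids:
            row = node["values"].get(sid)
            if row is None:
                n = 0
                damage = dup = dust = length = 0.0
                na = 1
            else:
                n = int(row["total_reads"])
                damage = row["damage5"]
                na = 1 if pd.isna(damage) else 0
                damage = 0.0 if pd.isna(damage) else float(damage)
                dup = 0.0 if pd.isna(row["duplicity"]) else float(row["duplicity"])
                dust = 0.0 if pd.isna(row["mean_dust"]) else float(row["mean_dust"])
                length = 0.0 if pd.isna(row["mean_length"]) else float(row["mean_length"])
            reads[sid] = n
            if parent_reads is not None and n > parent_reads[sid]:
                raise ValueError(
                    f"taxon {name} ({taxid}): reads {n} exceed parent's {parent_reads[sid]} "
                    f"in sample {sid}"
                )
            per_attr["reads"].append(str(n))
            per_attr["damage"].append(f"{damage:.6g}")
            per_attr["duplicity"].append(f"{dup:.6g}")
            per_attr["dust"].append(f"{dust:.6g}")
            per_attr["length"].append(f"{length:.6g}")
            per_attr["damage_na"].append(str(na))
        for attr_name, _ in KRONA_ATTRIBUTES:
            holder = ET.SubElement(el, attr_name)
            for v in per_attr[attr_name]:
                ET.SubElement(holder, "val").text = v
        holder = ET.SubElement(el, "damage_na")
        for v in per_attr["damage_na"]:
            ET.SubElement(holder, "val").text = v
        for child in sorted(node["children"].values(), key=lambda c: c["entry"]):
            emit(child, el, reads)

    emit(root_node, krona, None)
    tree = ET.ElementTree(krona)
    ET.indent(tree)
    tree.write(out_path, xml_declaration=True, encoding="unicode")
    return tree


@dataclass
class DamageSeries:
    sample: str
    offsets: List[int]
    freq5: List[float]  # 5' C->T by offset
    freq3: List[float]  # 3' C->T (ss) or G->A (ds) by offset


def damage_series(table: SubsTable, stranded: str, max_offset: int = 15, sample: str = "") -> DamageSeries:
    offsets = list(range(1, max_offset + 1))
    f5 = [table.frequency("5p", o, "C", "T") or 0.0 for o in offsets]
    if stranded == "ss":
        f3 = [table.frequency("3p", o, "C", "T") or 0.0 for o in offsets]
    else:
        f3 = [table.frequency("3p", o, "G", "A") or 0.0 for o in offsets]
    return DamageSeries(sample=sample, offsets=offsets, freq5=f5, freq3=f3)


def render_damage_plot(
    subs_paths: Dict[str, str],
    taxid: str,
    out_path: str,
    stranded: str = "ds",
    max_offset: int = 15,
) -> List[DamageSeries]:
    """Overlayed deamination curves for one taxon across samples.

    Raises KeyError listing available taxa when the taxon is absent from
    every substitution file.
    """
    series: List[DamageSeries] = []
    available: Set[str] = set()
    for sid, path in subs_paths.items():
        tables = read_subs_file(path)
        available.update(tables)
        if taxid in tables:
            _, table = tables[taxid]
            series.append(damage_series(table, stranded, max_offset, sample=sid))
    if not series:
        raise KeyError(
            f"taxid {taxid} not found in any substitution file; available: {sorted(available)}"
        )
    fig, (ax5, ax3) = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for s in series:
        ax5.plot(s.offsets, s.freq5, marker="o", label=s.sample)
        ax3.plot([-o for o in s.offsets][::-1], s.freq3[::-1], marker="o", label=s.sample)
    ax5.set_xlabel("distance from 5' end")
    ax5.set_ylabel("C->T frequency")
    label3 = "C->T" if stranded == "ss" else "G->A"
    ax3.set_xlabel("distance from 3' end")
    ax3.set_title(f"3' {label3}")
    ax5.set_title("5' C->T")
    ax5.legend()
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    return series


@dataclass
class BamInfo:
    sample: str
    lengths: List[int]
    mismatches: List[int]


def collect_bam_info(bam_path: str, sample: str = "") -> BamInfo:
    """Per-read full length and per-read mismatch count (NM of the first
    alignment of each read group)."""
    lengths: List[int] = []
    mism: List[int] = []
    with pysam.AlignmentFile(bam_path, "rb", check_sq=False) as bam:
        current = None
        for aln in bam:
            if aln.is_unmapped or aln.query_name == current:
                continue
            current = aln.query_name
            lengths.append(len(aln.query_sequence or ""))
            try:
                mism.append(int(aln.get_tag("NM")))
            except KeyError:
                mism.append(0)
    return BamInfo(sample=sample, lengths=lengths, mismatches=mism)


def render_baminfo_plot(bam_paths: Dict[str, str], out_path: str) -> List[BamInfo]:
    """Read length and mismatch histograms, one series per sample."""
    infos = [collect_bam_info(path, sample=sid) for sid, path in bam_paths.items()]
    fig, (axl, axm) = plt.subplots(1, 2, figsize=(9, 4))
    for info in infos:
        axl.hist(info.lengths, bins=range(0, max(info.lengths, default=1) + 2), alpha=0.5,
                 label=info.sample)
        axm.hist(info.mismatches, bins=range(0, max(info.mismatches, default=0) + 2), alpha=0.5,
                 label=info.sample)
    axl.set_xlabel("read length")
    axl.set_ylabel("reads")
    axm.set_xlabel("mismatches per read (NM)")
    axl.legend()
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    return infos
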