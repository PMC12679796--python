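"""Deterministic synthetic fixtures: toy taxonomy, references, damaged
reads, and matched BAM/LCA pairs.

Everything is seeded, so a fixed :class:`FixtureSpec` reproduces identical
files.  Reads carry truth labels (source taxon, true reference segment per
alignment, injected damage positions) so downstream stages can be tested
against exact oracles without any external data.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import pysam

from .primitives import reverse_complement
from .taxonomy import TaxNode

_BASES = "ACGT"


@dataclass(frozen=True)
class ToyTaxon:
    taxid: str
    name: str
    rank: str
    parent: Optional[str]  # taxid of parent; None for root


def toy_taxonomy() -> Dict[str, ToyTaxon]:
    """A small fixed taxonomy: two families under one order, plus the
    order/class/root spine, three species total."""
    taxa = [
        ToyTaxon("1", "root", "no rank", None),
        ToyTaxon("10", "Toyclassia", "class", "1"),
        ToyTaxon("100", "Toyorder", "order", "10"),
        ToyTaxon("1000", "Alphaceae", "family", "100"),
        ToyTaxon("1100", "Alphagenus", "genus", "1000"),
        ToyTaxon("1110", "Alphagenus primus", "species", "1100"),
        ToyTaxon("1120", "Alphagenus secundus", "species", "1100"),
        ToyTaxon("2000", "Betaceae", "family", "100"),
        ToyTaxon("2100", "Betagenus", "genus", "2000"),
        ToyTaxon("2110", "Betagenus tertius", "species", "2100"),
    ]
    return {t.taxid: t for t in taxa}


def taxonomy_path(taxa: Dict[str, ToyTaxon], taxid: str) -> Tuple[TaxNode, ...]:
    """Path from ``taxid`` up to the root, assigned node first."""
    path: List[TaxNode] = []
    cur: Optional[str] = taxid
    while cur is not None:
        t = taxa[cur]
        path.append(TaxNode(taxid=t.taxid, name=t.name, rank=t.rank))
        cur = t.parent
    return tuple(path)


@dataclass
class FixtureSpec:
    """Knobs of the generator; seed fixed => byte-identical outputs."""

    seed: int = 0
    ref_length: int = 1200
    reads_per_node: Dict[str, int] = field(
        default_factory=lambda: {"1110": 8, "1120": 6, "1100": 4, "2110": 7, "100": 3}
    )
    read_length: Tuple[int, int] = (34, 60)
    damage_amplitude: float = 0.0  # d0: terminal deamination probability
    damage_decay: float = 0.5  # r: geometric decay per offset
    stranded: str = "ds"
    error_rate: float = 0.0
    extra_alignment_prob: float = 0.3  # chance of a second (cross-species) alignment
    reverse_prob: float = 0.5
    softclip_prob: float = 0.0
    indel_prob: float = 0.0
    lowcomplexity_fraction: float = 0.0  # fraction of reads replaced by poly-T
    species_divergence: float = 0.03  # per-base mutation between sibling refs
    lca_metadata_suffix: bool = True  # append ":len:seq" to LCA read fields

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)


@dataclass
class SimAlignment:
    reference_name: str
    pos: int  # 0-based reference start
    is_reverse: bool
    cigar: Tuple[Tuple[int, int], ...]
    md: str
    nm: int
    score: int
    true_reference_segment: str
    stored_query: str


@dataclass
class SimRead:
    read_id: str
    sequence: str  # molecule orientation (as sequenced)
    source_species: str
    assigned_taxid: str
    damage_offsets5: Tuple[int, ...]
    damage_offsets3: Tuple[int, ...]
    alignments: List[SimAlignment]


@dataclass
class SimulatedFixture:
    spec: FixtureSpec
    taxa: Dict[str, ToyTaxon]
    references: Dict[str, str]  # reference name -> sequence
    reads: List[SimRead]

    def species_for(self, taxid: str) -> List[str]:
        """Leaf species at or below a node."""
        out = []
        for t in self.taxa.values():
            if t.rank != "species":
                continue
            cur: Optional[str] = t.taxid
            while cur is not None:
                if cur == taxid:
                    out.append(t.taxid)
                    break
                cur = self.taxa[cur].parent
        return out


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def _mutate(rng: random.Random, seq: str, rate: float) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(rng.choice([b for b in _BASES if b != ch]))
        else:
            out.append(ch)
    return "".join(out)


def _make_references(spec: FixtureSpec, taxa: Dict[str, ToyTaxon], rng: random.Random) -> Dict[str, str]:
    """One reference per species; siblings are mutated copies of a family
    ancestor so cross-species alignments stay plausible."""
    refs: Dict[str, str] = {}
    families: Dict[str, List[str]] = {}
    for t in taxa.values():
        if t.rank != "species":
            continue
        fam = t.taxid
        while taxa[fam].rank != "family":
            fam = taxa[fam].parent  # type: ignore[assignment]
        families.setdefault(fam, []).append(t.taxid)
    for fam, species in sorted(families.items()):
        ancestor = _random_seq(rng, spec.ref_length)
        for sp in sorted(species):
            refs[f"ref_{sp}"] = _mutate(rng, ancestor, spec.species_divergence)
    return refs


def _apply_damage(
    rng: random.Random, seq: str, spec: FixtureSpec
) -> Tuple[str, Tuple[int, ...], Tuple[int, ...]]:
    """Inject terminal deamination into a molecule-oriented sequence.

    5' offset i (1-based): C->T with probability d0 * r**(i-1).
    3' end: C->T for ss chemistry, G->A for ds.
    """
    d0, r = spec.damage_amplitude, spec.damage_decay
    if d0 <= 0:
        return seq, (), ()
    bases = list(seq)
    L = len(bases)
    hits5: List[int] = []
    hits3: List[int] = []
    for i in range(L):
        p5 = d0 * r**i
        if bases[i] == "C" and rng.random() < p5:
            bases[i] = "T"
            hits5.append(i + 1)
            continue
        j = L - 1 - i  # 3' offset of position i is j+1
        p3 = d0 * r**j
        if spec.stranded == "ss":
            if bases[i] == "C" and rng.random() < p3:
                bases[i] = "T"
                hits3.append(j + 1)
        else:
            if bases[i] == "G" and rng.random() < p3:
                bases[i] = "A"
                hits3.append(j + 1)
    return "".join(bases), tuple(hits5), tuple(hits3)


def _gapless_md_nm(query_core: str, ref_segment: str) -> Tuple[str, int]:
    """MD tag and mismatch count of a gapless core alignment."""
    md: List[str] = []
    run = 0
    nm = 0
    for q, r in zip(query_core, ref_segment):
        if q == r:
            run += 1
        else:
            md.append(str(run))
            md.append(r)
            run = 0
            nm += 1
    md.append(str(run))
    return "".join(md), nm


def _build_alignment(
    stored_query: str,
    ref: str,
    ref_name: str,
    pos: int,
    is_reverse: bool,
    cigar: Tuple[Tuple[int, int], ...],
) -> SimAlignment:
    """Derive MD/NM/AS for a stored query aligned at ``pos`` with ``cigar``.

    Supports M (0), I (1), D (2) and S (4) operations.  AS is a simple
    match/mismatch/gap score so that lower-divergence alignments win.
    """
    qpos = 0
    rpos = pos
    md: List[str] = []
    run = 0
    nm = 0
    matches = 0
    gaps = 0
    ref_segment: List[str] = []
    for op, length in cigar:
        if op == 0:  # M
            for _ in range(length):
                q = stored_query[qpos]
                r = ref[rpos]
                ref_segment.append(r)
                if q == r:
                    run += 1
                    matches += 1
                else:
                    md.append(str(run))
                    md.append(r)
                    run = 0
                    nm += 1
                qpos += 1
                rpos += 1
        elif op == 1:  # I
            qpos += length
            nm += length
            gaps += 1
        elif op == 2:  # D
            md.append(str(run))
            run = 0
            deleted = ref[rpos : rpos + length]
            md.append("^" + deleted)
            ref_segment.append(deleted)
            nm += length
            gaps += 1
            rpos += length
        elif op == 4:  # S
            qpos += length
        else:
            raise ValueError(f"unsupported simulated CIGAR op {op}")
    md.append(str(run))
    score = 2 * matches - 5 * nm - 6 * gaps
    return SimAlignment(
        reference_name=ref_name,
        pos=pos,
        is_reverse=is_reverse,
        cigar=cigar,
        md="".join(md),
        nm=nm,
        score=score,
        true_reference_segment="".join(ref_segment),
        stored_query=stored_query,
    )


def simulate_damaged_reads(spec: FixtureSpec) -> SimulatedFixture:
    """Draw reads from the toy references with injected terminal damage,
    sequencing error, and optional soft clips / indels / extra alignments."""
    rng = random.Random(spec.seed)
    taxa = toy_taxonomy()
    refs = _make_references(spec, taxa, rng)
    fixture = SimulatedFixture(spec=spec, taxa=taxa, references=refs, reads=[])

    read_no = 0
    for assigned, count in sorted(spec.reads_per_node.items()):
        species_pool = fixture.species_for(assigned)
        if not species_pool:
            raise ValueError(f"node {assigned} has no leaf species")
        for _ in range(count):
            rid = f"read{read_no:05d}"
            read_no += 1
            source = rng.choice(species_pool)
            ref_name = f"ref_{source}"
            ref = refs[ref_name]
            length = rng.randint(*spec.read_length)
            pos = rng.randrange(0, len(ref) - length)
            is_reverse = rng.random() < spec.reverse_prob

            fragment = ref[pos : pos + length]
            molecule = reverse_complement(fragment) if is_reverse else fragment
            if spec.lowcomplexity_fraction and rng.random() < spec.lowcomplexity_fraction:
                molecule = "T" * length
            molecule, hits5, hits3 = _apply_damage(rng, molecule, spec)
            if spec.error_rate > 0:
                molecule = _mutate(rng, molecule, spec.error_rate)

            stored = reverse_complement(molecule) if is_reverse else molecule
            cigar: Tuple[Tuple[int, int], ...] = ((0, length),)
            aln_pos = pos
            # optional structural decoration of the true alignment
            u = rng.random()
            if spec.softclip_prob and u < spec.softclip_prob:
                clip = rng.randint(2, 6)
                pad = _random_seq(rng, clip)
                if rng.random() < 0.5:
                    stored = pad + stored
                    cigar = ((4, clip), (0, length))
                else:
                    stored = stored + pad
                    cigar = ((0, length), (4, clip))
            elif spec.indel_prob and u < spec.softclip_prob + spec.indel_prob:
                cut = rng.randint(5, length - 5)
                if rng.random() < 0.5:  # insertion into the read
                    stored = stored[:cut] + rng.choice(_BASES) + stored[cut:]
                    cigar = ((0, cut), (1, 1), (0, length - cut))
                else:  # deletion: read skips one reference base
                    stored = stored[:cut] + stored[cut + 1 :]
                    cigar = ((0, cut), (2, 1), (0, length - cut - 1))

            alignments = [_build_alignment(stored, ref, ref_name, aln_pos, is_reverse, cigar)]
            if rng.random() < spec.extra_alignment_prob:
                # gapless secondary alignment to a sibling reference at the
                # homologous coordinate (references are mutated copies)
                siblings = [n for n in sorted(refs) if n != ref_name]
                other = rng.choice(siblings)
                qlen = len(stored)
                opos = min(pos, len(refs[other]) - qlen)
                alignments.append(
                    _build_alignment(stored, refs[other], other, opos, is_reverse, ((0, qlen),))
                )

            fixture.reads.append(
                SimRead(
                    read_id=rid,
                    sequence=molecule,
                    source_species=source,
                    assigned_taxid=assigned,
                    damage_offsets5=hits5,
                    damage_offsets3=hits3,
                    alignments=alignments,
                )
            )
    return fixture


def write_lca_file(fixture: SimulatedFixture, path: str) -> None:
    spec = fixture.spec
    with open(path, "w") as fh:
        for read in fixture.reads:
            field0 = read.read_id
            if spec.lca_metadata_suffix:
                field0 = f"{read.read_id}:{len(read.sequence)}:{read.sequence}"
            entries = [n.entry() for n in taxonomy_path(fixture.taxa, read.assigned_taxid)]
            fh.write("\t".join([field0] + entries) + "\n")


def write_bam_file(fixture: SimulatedFixture, path: str) -> None:
    """Read-name-grouped BAM with MD/NM/AS tags against the toy references."""
    ref_names = sorted(fixture.references)
    header = {
        "HD": {"VN": "1.6", "SO": "queryname"},
        "SQ": [{"SN": n, "LN": len(fixture.references[n])} for n in ref_names],
    }
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for read in fixture.reads:
            for i, sim in enumerate(read.alignments):
                a = pysam.AlignedSegment(bam.header)
                a.query_name = read.read_id
                a.query_sequence = sim.stored_query
                a.flag = (16 if sim.is_reverse else 0) | (256 if i > 0 else 0)
                a.reference_id = ref_names.index(sim.reference_name)
                a.reference_start = sim.pos
                a.mapping_quality = 30
                a.cigartuples = list(sim.cigar)
                a.query_qualities = pysam.qualitystring_to_array("I" * len(sim.stored_query))
                a.set_tag("MD", sim.md)
                a.set_tag("NM", sim.nm)
                a.set_tag("AS", sim.score)
                bam.write(a)


def emit_fixture_pair(fixture: SimulatedFixture, bam_path: str, lca_path: str) -> Tuple[str, str]:
    """Write the matched BAM and LCA files; both parse with this package's
    own readers, in the same read order."""
    write_bam_file(fixture, bam_path)
    write_lca_file(fixture, lca_path)
    return bam_path, lca_path
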