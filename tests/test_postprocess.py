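import xml.etree.ElementTree as ET

import pandas as pd
import pytest

from paleodam.compute import ComputeConfig, compute
from paleodam.postprocess import (
    collect_bam_info,
    combine_tables,
    damage_series,
    extract_taxa_bam,
    krona_xml,
    load_stats_table,
    render_baminfo_plot,
    render_damage_plot,
)
from paleodam.compute import read_subs_file
from paleodam.simulate import FixtureSpec, emit_fixture_pair, simulate_damaged_reads
from paleodam.taxonomy import iter_lca_file

from conftest import open_bam


def toy_table(taxid="9604", name="Fam", reads=100, damage5=0.1, path="9604:Fam:family;1:root:no rank"):
    return pd.DataFrame(
        [
            {
                "name": name, "taxid": taxid, "total_reads": reads, "duplicity": 1.0,
                "mean_dust": 5.0, "damage5": damage5, "damage3": 0.1, "mean_length": 40.0,
                "ani": 0.98, "mean_read_gc": 0.5, "mean_ref_gc": 0.5, "unique_kmers": 1000.0,
                "unaggregated_reads": reads, "tax_path": path,
            }
        ]
    )


class TestCombine:
    def test_read_weighted_mean(self):
        t1 = toy_table(reads=100, damage5=0.1)
        t2 = toy_table(reads=300, damage5=0.3)
        out = combine_tables({"s1": t1, "s2": t2})
        row = out.iloc[0]
        assert row["reads_s1"] == 100 and row["reads_s2"] == 300
        assert row["damage5_wmean"] == pytest.approx((100 * 0.1 + 300 * 0.3) / 400)
        assert row["damage5_wmean"] == pytest.approx(0.25)

    def test_taxon_absent_from_one_sample(self):
        t1 = toy_table(taxid="9604")
        t2 = toy_table(taxid="9999", name="Other", path="9999:Other:family;1:root:no rank")
        out = combine_tables({"s1": t1, "s2": t2}).set_index("taxid")
        assert out.loc["9604", "reads_s2"] == 0
        assert pd.isna(out.loc["9604", "damage5_s2"])
        # weighted mean over samples where the metric is non-NA
        assert out.loc["9604", "damage5_wmean"] == pytest.approx(0.1)

    def test_single_table_identity(self):
        t1 = toy_table()
        out = combine_tables({"only": t1})
        assert out.iloc[0]["damage5_only"] == pytest.approx(0.1)
        assert out.iloc[0]["damage5_wmean"] == pytest.approx(0.1)

    def test_permutation_invariance(self):
        t1, t2 = toy_table(reads=100, damage5=0.1), toy_table(reads=300, damage5=0.3)
        a = combine_tables({"s1": t1, "s2": t2})
        b = combine_tables({"s2": t2, "s1": t1})
        assert a["damage5_wmean"].equals(b["damage5_wmean"])
        assert set(a.columns) == set(b.columns)

    def test_no_tables_rejected(self):
        with pytest.raises(ValueError):
            combine_tables({})


@pytest.fixture(scope="module")
def extract_fixture(tmp_path_factory):
    spec = FixtureSpec(
        seed=55,
        reads_per_node={"1110": 6, "1100": 4, "2110": 6},
        extra_alignment_prob=0.5,
    )
    fx = simulate_damaged_reads(spec)
    d = tmp_path_factory.mktemp("extract")
    bam, lca = emit_fixture_pair(fx, str(d / "e.bam"), str(d / "e.lca"))
    return fx, bam, lca, d


class TestExtract:
    def test_or_below_semantics(self, extract_fixture):
        fx, bam, lca, d = extract_fixture
        out = str(d / "genus.bam")
        extract_taxa_bam(bam, lca, {"1100"}, out)
        with open_bam(out) as fh:
            got = {a.query_name for a in fh}
        expected = {r.read_id for r in fx.reads if r.assigned_taxid in {"1100", "1110"}}
        assert got == expected

    def test_best_only_single_alignment_per_read(self, extract_fixture):
        fx, bam, lca, d = extract_fixture
        out = str(d / "best.bam")
        extract_taxa_bam(bam, lca, {"1100"}, out, best_only=True, seed=3)
        with open_bam(out) as fh:
            names = [a.query_name for a in fh]
        assert len(names) == len(set(names))
        # reproducible under fixed seed
        out2 = str(d / "best2.bam")
        extract_taxa_bam(bam, lca, {"1100"}, out2, best_only=True, seed=3)
        with open_bam(out) as a, open_bam(out2) as b:
            assert [x.to_string() for x in a] == [x.to_string() for x in b]

    def test_header_subset_to_used_references(self, extract_fixture):
        fx, bam, lca, d = extract_fixture
        out = str(d / "hdr.bam")
        extract_taxa_bam(bam, lca, {"2100"}, out)
        with open_bam(out) as fh:
            refs_in_header = set(fh.references)
            used = {a.reference_name for a in fh}
        assert refs_in_header == used

    def test_top_reference_only(self, extract_fixture):
        fx, bam, lca, d = extract_fixture
        out = str(d / "top.bam")
        extract_taxa_bam(bam, lca, {"1100"}, out, top_reference_only=True)
        with open_bam(out) as fh:
            refs = {a.reference_name for a in fh}
        assert len(refs) == 1

    def test_absent_taxid_empty_bam(self, extract_fixture):
        fx, bam, lca, d = extract_fixture
        out = str(d / "empty.bam")
        n = extract_taxa_bam(bam, lca, {"424242"}, out)
        assert n == 0
        with open_bam(out) as fh:
            assert list(fh) == []

    def test_extract_is_a_fixed_point(self, extract_fixture, tmp_path):
        fx, bam, lca, d = extract_fixture
        out1 = str(tmp_path / "x1.bam")
        extract_taxa_bam(bam, lca, {"2100"}, out1)
        # restrict the lca to the extracted reads, in order
        kept = {r.read_id for r in fx.reads if r.assigned_taxid in {"2100", "2110"}}
        sub_lca = str(tmp_path / "x.lca")
        with open(sub_lca, "w") as fh:
            for _, a in iter_lca_file(lca):
                if a.read_id in kept:
                    from paleodam.taxonomy import format_lca_line
                    fh.write(format_lca_line(a) + "\n")
        out2 = str(tmp_path / "x2.bam")
        extract_taxa_bam(out1, sub_lca, {"2100"}, out2)
        with open_bam(out1) as a, open_bam(out2) as b:
            assert [x.to_string() for x in a] == [x.to_string() for x in b]


@pytest.fixture(scope="module")
def computed_samples(tmp_path_factory):
    d = tmp_path_factory.mktemp("samples")
    paths = {}
    for sid, seed in (("s1", 71), ("s2", 72)):
        spec = FixtureSpec(seed=seed, reads_per_node={"1110": 8, "2110": 6},
                           damage_amplitude=0.25, extra_alignment_prob=0.0)
        fx = simulate_damaged_reads(spec)
        bam, lca = emit_fixture_pair(fx, str(d / f"{sid}.bam"), str(d / f"{sid}.lca"))
        tsv, subs = str(d / f"{sid}.tsv"), str(d / f"{sid}.subs")
        compute(bam, lca, tsv, subs, ComputeConfig(stranded="ds"))
        paths[sid] = {"bam": bam, "tsv": tsv, "subs": subs}
    return d, paths


class TestKrona:
    def test_magnitudes_match_tsv_total_reads(self, computed_samples, tmp_path):
        d, paths = computed_samples
        tables = {sid: load_stats_table(p["tsv"]) for sid, p in paths.items()}
        out = str(tmp_path / "k.xml")
        krona_xml(tables, out)
        tree = ET.parse(out)  # also proves well-formedness
        sample_ids = [el.text for el in tree.getroot().find("datasets")]
        assert sample_ids == list(tables)
        for node in tree.getroot().iter("node"):
            name = node.get("name")
            reads_vals = [int(v.text) for v in node.find("reads")]
            for sid, vals in zip(sample_ids, reads_vals):
                df = tables[sid].set_index("name")
                if name in df.index:
                    assert vals == df.loc[name, "total_reads"]
                else:
                    assert vals == 0

    def test_structure_matches_importxml_dialect(self, computed_samples, tmp_path):
        d, paths = computed_samples
        tables = {sid: load_stats_table(p["tsv"]) for sid, p in paths.items()}
        out = str(tmp_path / "k2.xml")
        krona_xml(tables, out)
        root = ET.parse(out).getroot()
        assert root.tag == "krona"
        attrs = root.find("attributes")
        assert attrs.get("magnitude") == "reads"
        declared = [a.text for a in attrs]
        assert "reads" in declared and "damage" in declared
        color = root.find("color")
        assert color.get("attribute") == "damage"
        top = root.find("node")
        assert top is not None
        n_samples = len(root.find("datasets"))
        for node in root.iter("node"):
            assert len(node.find("reads")) == n_samples

    def test_parent_child_inversion_rejected(self, tmp_path):
        child = toy_table(taxid="9604", reads=50)
        parent_path = "1:root:no rank"
        bad = pd.concat([child], ignore_index=True)
        # root row with fewer reads than its child
        root_row = toy_table(taxid="1", name="root", reads=10, path=parent_path)
        table = pd.concat([bad, root_row], ignore_index=True)
        with pytest.raises(ValueError, match="Fam"):
            krona_xml({"s": table}, str(tmp_path / "bad.xml"))


class TestDamagePlot:
    def test_series_match_subs_file(self, computed_samples, tmp_path):
        d, paths = computed_samples
        subs = {sid: p["subs"] for sid, p in paths.items()}
        out = str(tmp_path / "dmg.svg")
        series = render_damage_plot(subs, "1110", out, stranded="ds")
        assert len(series) == 2
        for s in series:
            _name, table = read_subs_file(subs[s.sample])["1110"]
            expected = damage_series(table, "ds", sample=s.sample)
            assert s.freq5 == expected.freq5
            assert s.freq3 == expected.freq3
        assert (tmp_path / "dmg.svg").exists()

    def test_missing_taxid_lists_available(self, computed_samples, tmp_path):
        d, paths = computed_samples
        subs = {sid: p["subs"] for sid, p in paths.items()}
        with pytest.raises(KeyError, match="available"):
            render_damage_plot(subs, "nope", str(tmp_path / "x.svg"), stranded="ds")

    def test_empty_damage_node_flat_zero(self, tmp_path):
        spec = FixtureSpec(seed=91, reads_per_node={"1110": 6}, damage_amplitude=0.0,
                           extra_alignment_prob=0.0, error_rate=0.0, species_divergence=0.0)
        fx = simulate_damaged_reads(spec)
        bam, lca = emit_fixture_pair(fx, str(tmp_path / "z.bam"), str(tmp_path / "z.lca"))
        compute(bam, lca, str(tmp_path / "z.tsv"), str(tmp_path / "z.subs"),
                ComputeConfig(stranded="ds"))
        series = render_damage_plot({"s": str(tmp_path / "z.subs")}, "1110",
                                    str(tmp_path / "z.svg"), stranded="ds")
        assert all(v == 0.0 for v in series[0].freq5[1:])  # offset 1 C->T absent too
        assert series[0].freq5[0] == 0.0


class TestBamInfoPlot:
    def test_totals_match_read_counts(self, computed_samples, tmp_path):
        d, paths = computed_samples
        bams = {sid: p["bam"] for sid, p in paths.items()}
        infos = render_baminfo_plot(bams, str(tmp_path / "info.svg"))
        for info in infos:
            with open_bam(bams[info.sample]) as fh:
                reads = len({a.query_name for a in fh})
            assert len(info.lengths) == reads
            assert len(info.mismatches) == reads

    def test_perfect_match_fixture_point_mass_at_zero(self, tmp_path):
        spec = FixtureSpec(seed=92, reads_per_node={"1110": 5}, damage_amplitude=0.0,
                           error_rate=0.0, extra_alignment_prob=0.0)
        fx = simulate_damaged_reads(spec)
        bam, lca = emit_fixture_pair(fx, str(tmp_path / "p.bam"), str(tmp_path / "p.lca"))
        info = collect_bam_info(bam, sample="p")
        assert info.mismatches == [0] * 5
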