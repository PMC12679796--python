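import pysam
import pytest

from paleodam.simulate import FixtureSpec, emit_fixture_pair, simulate_damaged_reads
from paleodam.taxonomy import iter_lca_file


@pytest.fixture(scope="session")
def clean_fixture(tmp_path_factory):
    """No damage, no errors, single alignment per read; every assigned node
    at/below family with >= 5 aggregated reads, so shrink is a no-op."""
    spec = FixtureSpec(
        seed=11,
        reads_per_node={"1110": 6, "1120": 6, "2110": 7},
        extra_alignment_prob=0.0,
        damage_amplitude=0.0,
        error_rate=0.0,
    )
    fx = simulate_damaged_reads(spec)
    d = tmp_path_factory.mktemp("clean")
    bam, lca = emit_fixture_pair(fx, str(d / "in.bam"), str(d / "in.lca"))
    return fx, bam, lca


@pytest.fixture(scope="session")
def mixed_fixture(tmp_path_factory):
    """Assignments above and below family, support straddling 5, multiple
    alignments, indels/soft clips, mild damage."""
    spec = FixtureSpec(
        seed=23,
        reads_per_node={"1110": 3, "1100": 6, "2110": 7, "100": 4, "10": 2},
        extra_alignment_prob=0.4,
        damage_amplitude=0.2,
        error_rate=0.005,
        softclip_prob=0.1,
        indel_prob=0.1,
    )
    fx = simulate_damaged_reads(spec)
    d = tmp_path_factory.mktemp("mixed")
    bam, lca = emit_fixture_pair(fx, str(d / "in.bam"), str(d / "in.lca"))
    return fx, bam, lca


def lca_assignments(path):
    return [a for _, a in iter_lca_file(path)]


def open_bam(path):
    return pysam.AlignmentFile(path, "rb", check_sq=False)
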