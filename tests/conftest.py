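import pytest

from tailprimer.fixtures import FixtureSpec, generate_fixture
from tailprimer.intervals import GenomicInterval
from tailprimer.annotation import TranscriptModel, GeneModel


@pytest.fixture(scope="session")
def fixture_small(tmp_path_factory):
    """A small deterministic synthetic dataset shared across unit tests."""
    outdir = tmp_path_factory.mktemp("fixture_small")
    spec = FixtureSpec(seed=7, n_genes=8, decoy_repeats=1)
    manifest = generate_fixture(spec, outdir)
    return manifest


@pytest.fixture
def two_exon_plus():
    return TranscriptModel(
        transcript_id="t+",
        gene_id="g+",
        exons=[
            GenomicInterval("chr1", 100, 200, "+"),
            GenomicInterval("chr1", 300, 400, "+"),
        ],
    )


@pytest.fixture
def two_exon_minus():
    return TranscriptModel(
        transcript_id="t-",
        gene_id="g-",
        exons=[
            GenomicInterval("chr1", 100, 200, "-"),
            GenomicInterval("chr1", 300, 400, "-"),
        ],
    )


@pytest.fixture
def gene_one_exon():
    t1 = TranscriptModel(
        "tx1", "G1", [GenomicInterval("chr1", 150, 400, "+")]
    )
    return GeneModel("G1", [t1])
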