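import pytest

from cronoscan.genemodels import ExonRecord, GenomeSequence, TranscriptModel
from cronoscan.synthetic_data import SimulationConfig, make_toy_gene


@pytest.fixture(scope="session")
def toy():
    """Default miniature titin-like gene (12 exons, internal promoter)."""
    return make_toy_gene(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def toy_config():
    return SimulationConfig(seed=1)


@pytest.fixture
def two_exon_model():
    """Handcrafted 2-exon plus-strand gene: spliced CDS is ATGAAATAA.

    Layout on chrX: CC | ATGAA | GTCCCCAG | ATAA | CC
    positions:      0-2  2-7     7-15       15-19  19-21
    """
    genome = GenomeSequence({"chrX": "CCATGAAGTCCCCAGATAACC"})
    transcript = TranscriptModel(
        "mini",
        "+",
        [ExonRecord("chrX", 2, 7, 1), ExonRecord("chrX", 15, 19, 2)],
        cds_start=2,
        cds_end=19,
    )
    return genome, transcript
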