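import pytest
from hypothesis import settings

from crmscreen.io import GeneAnnotation, GenomicInterval, PeakSet

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def worked_gene() -> GeneAnnotation:
    """Single gene with TSS at 10 000 (the manual-trace CRM fixture)."""
    return GeneAnnotation.from_records([("geneA", "chr1", 10_000, "+")])


@pytest.fixture
def worked_peaks() -> list[PeakSet]:
    """Three TFs around the worked gene: TF1/TF2 overlap near the TSS, TF3
    sits alone 1.5 kb downstream."""
    return [
        PeakSet("TF1", [GenomicInterval("chr1", 9_900, 9_950)]),
        PeakSet("TF2", [GenomicInterval("chr1", 9_940, 9_990)]),
        PeakSet("TF3", [GenomicInterval("chr1", 11_500, 11_550)]),
    ]


@pytest.fixture
def four_gene_annotation() -> GeneAnnotation:
    return GeneAnnotation.from_records(
        [
            ("g1", "chr1", 10_000, "+"),
            ("g2", "chr1", 50_000, "-"),
            ("g3", "chr1", 90_000, "+"),
            ("g4", "chr1", 130_000, "+"),
        ]
    )
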