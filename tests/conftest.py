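import pytest

from mutscape import GeneModel, Interval


@pytest.fixture
def toy_gene() -> GeneModel:
    """30-nt gene: exon[0,10) intron[10,20) exon[20,30)."""
    return GeneModel(
        "toy",
        "A" * 10 + "C" * 10 + "G" * 10,
        exons=[Interval(0, 10), Interval(20, 30)],
        introns=[Interval(10, 20)],
    )
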