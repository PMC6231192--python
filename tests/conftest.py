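import pytest

from hervprox.locus_store import GenomicInterval, HervLocus, build_store


@pytest.fixture
def toy_store():
    """Six hand-placed loci on two chromosomes."""
    loci = [
        HervLocus(GenomicInterval("chr1", 1000, 1100, "+"), 1e-50, "L1"),
        HervLocus(GenomicInterval("chr1", 5000, 5200, "-"), 1e-20, "L2"),
        HervLocus(GenomicInterval("chr1", 9000, 9050, "+"), 1e-120, "L3"),
        HervLocus(GenomicInterval("chr2", 100, 200, "+"), 1e-80, "L4"),
        HervLocus(GenomicInterval("chr2", 3000, 3500, "-"), 1e-15, "L5"),
        HervLocus(GenomicInterval("chr2", 7000, 7010, "+"), 1e-200, "L6"),
    ]
    return build_store(loci)
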