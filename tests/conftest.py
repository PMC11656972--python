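import pytest

from covgap.io_formats import ContigSet
from covgap.simulate import random_sequence


@pytest.fixture(scope="session")
def small_contigs() -> ContigSet:
    """A 300-kb single-contig genome used by mapper/pipeline unit tests."""
    return ContigSet([("chr1", random_sequence(300_000, seed=42))])


@pytest.fixture()
def toy_contigs() -> ContigSet:
    return ContigSet([("c1", "AACGTTTACG"), ("c2", "GGGGCCCCAA")])
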