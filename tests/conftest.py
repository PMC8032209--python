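import pytest

from circmotif.model import ExonModel, Genome, GenomeSeq
from circmotif.simulate import SyntheticConfig, generate


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded run of the full generator, shared across the suite."""
    return generate(SyntheticConfig(seed=42))


@pytest.fixture
def toy_genome():
    # chr1: 90 bases, hand-typed so slices can be checked by eye;
    # exons sit at 11-20 (G), 31-40 (T) and 51-60 (GATTACAGAT)
    seq = (
        "ACGTACGTAC" "GGGGGGGGGG" "CATCATCATC"
        "TTTTTTTTTT" "AAAAAAAAAA" "GATTACAGAT"
        "CCCCCCCCCC" "TACAGATTAC" "AGATTACAGA"
    )
    return Genome([GenomeSeq("chr1", seq)])


@pytest.fixture
def toy_model_plus():
    # three 10-base exons at 11-20, 31-40, 51-60 (1-based inclusive)
    return ExonModel(
        "toyP", "chr1", "+", ((11, 20), (31, 40), (51, 60))
    )


@pytest.fixture
def toy_model_minus():
    # same exons, minus strand: transcript order descends the genome
    return ExonModel(
        "toyM", "chr1", "-", ((51, 60), (31, 40), (11, 20))
    )
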