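import pytest

from pmltcr.repertoire_io import ClonotypeRecord, SampleMetadata, build_cohort
from pmltcr.synthetic_cohort import SyntheticConfig, generate_cohort, scaled_config


@pytest.fixture
def tiny_records():
    return [
        ClonotypeRecord("S1", "CASSLGF", 3, chain="TRB"),
        ClonotypeRecord("S1", "CAVRDNF", 1, chain="TRA"),
        ClonotypeRecord("S2", "CASSLGF", 2, chain="TRB"),
        ClonotypeRecord("S2", "CASSQET", 4, chain="TRB"),
        ClonotypeRecord("S3", "CASSQET", 5, chain="TRB"),
    ]


@pytest.fixture
def tiny_metadata():
    return [
        SampleMetadata("S1", "P1", "L1", 1, subtype="proliferative", outcome="regressive"),
        SampleMetadata("S2", "P1", "L2", 1, subtype="proliferative", outcome="progressive/persistent"),
        SampleMetadata("S3", "P2", "L1", 1, subtype="other", outcome="unknown"),
    ]


@pytest.fixture
def tiny_cohort(tiny_records, tiny_metadata):
    return build_cohort(tiny_records, tiny_metadata)


@pytest.fixture(scope="session")
def default_cohort():
    """Study-scale synthetic cohort (50 patients, seed 17)."""
    return generate_cohort(SyntheticConfig())


@pytest.fixture(scope="session")
def small_cohort():
    """Scaled-down synthetic cohort used where full scale is unnecessary."""
    return generate_cohort(scaled_config(seed=3))
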