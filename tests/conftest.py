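import pytest
from hypothesis import settings

from foundertrace import datasets, extract_chromosomes
from foundertrace.cohort_io import MarkerDef, MarkerPanel

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def physical_panel():
    return datasets.load_panel("physical")


@pytest.fixture(scope="session")
def genetic_panel():
    return datasets.load_panel("genetic")


@pytest.fixture(scope="session")
def karachay_records(physical_panel):
    return datasets.load_cohort("karachay", physical_panel)


@pytest.fixture(scope="session")
def chechen_records(physical_panel):
    return datasets.load_cohort("chechen", physical_panel)


@pytest.fixture(scope="session")
def karachay_chromosomes(karachay_records, physical_panel):
    return extract_chromosomes(karachay_records, "c.1015G>A", physical_panel)


@pytest.fixture(scope="session")
def chechen_chromosomes(chechen_records, physical_panel):
    return extract_chromosomes(chechen_records, "c.518A>G", physical_panel)


@pytest.fixture(scope="session")
def recovery_panel():
    """Five markers flanking the locus at 2.1-20 cM (theta 0.02-0.17)."""
    return MarkerPanel(
        markers=(
            MarkerDef("M1", 10.0),
            MarkerDef("M2", 25.0),
            MarkerDef("M3", 32.1),
            MarkerDef("M4", 40.0),
            MarkerDef("M5", 45.0),
        ),
        locus_position=30.0,
        unit="genetic_cM",
    )
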