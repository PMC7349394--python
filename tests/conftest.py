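import numpy as np
import pytest

from pondpop import datasets
from pondpop.io_survey import HaplotypeCountTable, PondEnvironment


@pytest.fixture(scope="session")
def survey_table() -> HaplotypeCountTable:
    """The bundled 29-pond x 26-haplotype COI count matrix."""
    return datasets.load_haplotype_table()


@pytest.fixture(scope="session")
def survey_ponds() -> list[PondEnvironment]:
    return datasets.load_pond_environments()


@pytest.fixture(scope="session")
def printed_diversity():
    return datasets.load_printed_diversity()


@pytest.fixture(scope="session")
def overwintering_records():
    return datasets.load_overwintering_records()


def make_pond(site_id: str, **overrides) -> PondEnvironment:
    """A valid pond record with sensible defaults, for unit fixtures."""
    values = dict(
        site_id=site_id,
        latitude=36.2,
        longitude=137.9,
        altitude=800.0,
        surface_area=1000.0,
        perimeter=120.0,
        vegetation_grade="II",
        shoreline_vegetation_rate=50.0,
        concrete_revetment_rate=10.0,
        shore_gradient_mean=40.0,
        shore_gradient_sd=15.0,
        inflow_count=1,
        outflow_count=1,
        transparency_mean=60.0,
        tn_mean=0.0,
        nh4_mean=0.0,
        po4_mean=0.1,
    )
    values.update(overrides)
    return PondEnvironment(**values)


@pytest.fixture
def pond_factory():
    return make_pond
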