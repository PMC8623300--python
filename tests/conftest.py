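import pytest

from phenoscore import OrganCounts, SpecimenRecord, fixture_small


def make_record(
    rid="S1",
    manual=(10, 5, 2, 1),
    predicted=None,
    year=1960,
    doy=180,
    latitude=38.0,
    longitude=-120.5,
    elevation=1500.0,
    spring_tmax=12.0,
    winter_ppt=600.0,
):
    """One specimen with compact defaults; counts given as 4-tuples."""
    return SpecimenRecord(
        id=rid, year=year, doy=doy, latitude=latitude, longitude=longitude,
        elevation=elevation, spring_tmax=spring_tmax, winter_ppt=winter_ppt,
        manual_counts=OrganCounts(*manual),
        predicted_counts=OrganCounts(*predicted) if predicted is not None else None,
    )


@pytest.fixture(scope="session")
def small_collection():
    """The 25-sheet deterministic collection used throughout the docs."""
    return fixture_small()
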