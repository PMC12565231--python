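import numpy as np
import pytest

from parademog import (
    ExposureEvent,
    IndividualRecord,
    SEASONS,
    WeatherSeries,
)


def constant_weather(season: str, n_days: int) -> WeatherSeries:
    """Weather pinned at the seasonal means (the zero-noise limit)."""
    c = SEASONS[season]
    ones = np.ones(n_days)
    return WeatherSeries(
        day=np.arange(n_days),
        tmax=ones * c.tmax,
        tmin=ones * c.tmin,
        tmean=ones * c.tmean,
        rhmax=ones * c.rhmax,
        rhmin=ones * c.rhmin,
        rhmean=ones * c.rhmean,
    )


def make_female(fid, cohort, death, exposures=()):
    return IndividualRecord(
        female_id=fid,
        cohort_id=cohort,
        age_at_death=death,
        exposures=tuple(
            ExposureEvent(maternal_age=a, hosts_exposed=90, daughters=d, sons=s)
            for a, d, s in exposures
        ),
    )


@pytest.fixture
def two_female_cohort():
    """Two females dying at ages 2 and 4, no exposures."""
    return [make_female("f1", "c", 2), make_female("f2", "c", 4)]


@pytest.fixture
def reproducing_cohort():
    """Small cohort with exposures at known ages."""
    return [
        make_female("f1", "c", 3, [(1, 4, 2)]),
        make_female("f2", "c", 5, [(1, 3, 3), (3, 2, 1)]),
        make_female("f3", "c", 2, [(1, 0, 1)]),
    ]


def random_cohort(rng: np.random.Generator, n=12, cohort="rand"):
    """Arbitrary valid cohort for property tests."""
    records = []
    for i in range(n):
        death = int(rng.integers(1, 15))
        ages = sorted(rng.choice(death, size=rng.integers(0, death), replace=False))
        expo = []
        for a in ages:
            d = int(rng.integers(0, 6))
            s = int(rng.integers(0, 6))
            expo.append((int(a), d, s))
        records.append(make_female(f"f{i}", cohort, death, expo))
    return records
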