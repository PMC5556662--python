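import datetime as dt

import pytest

from claimsinc.cohort import CohortSpec, build_cohort
from claimsinc.data import ClaimsTables, PersonRecord
from claimsinc.simulate import SimulationConfig, generate_population


def full_coverage_person(pid: str, sex: str = "F", birth_year: int = 1950,
                         state: str = "NW", death_date=None) -> PersonRecord:
    return PersonRecord(
        person_id=pid, sex=sex, birth_year=birth_year, state=state,
        spells=((dt.date(2005, 1, 1), dt.date(2014, 12, 31)),),
        death_date=death_date,
    )


@pytest.fixture(scope="session")
def default_sim():
    """One moderately sized default-noise population shared across tests."""
    config = SimulationConfig(n_persons=12_000, seed=42)
    tables, truth = generate_population(config)
    return config, tables, truth


@pytest.fixture(scope="session")
def default_sim_cohort(default_sim):
    _, tables, _ = default_sim
    return build_cohort(tables, CohortSpec())


def tiny_tables(persons=(), outpatient=(), inpatient=(), procedures=()) -> ClaimsTables:
    return ClaimsTables.from_records(persons, outpatient, inpatient, procedures)
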