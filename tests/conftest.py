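import datetime as dt

import pandas as pd
import pytest

from retriage import linkage, cohort
from retriage.hospitals import HospitalDirectory
from retriage.synthetic_data import (
    SimulationConfig,
    generate_hospital_directory,
    generate_encounters,
)


@pytest.fixture(scope="session")
def clean_config():
    """Mid-size population with full RLN coverage so linkage is exact."""
    return SimulationConfig(n_patients=5000, seed=11, p_missing_rln=0.0, p_duplicate=0.1)


@pytest.fixture(scope="session")
def clean_directory(clean_config):
    return generate_hospital_directory(clean_config)


@pytest.fixture(scope="session")
def clean_dataset(clean_config, clean_directory):
    return generate_encounters(clean_config, clean_directory)


@pytest.fixture(scope="session")
def clean_cohort(clean_config, clean_directory, clean_dataset):
    ed, ip, truth = clean_dataset
    ed, _ = linkage.deduplicate_records(ed)
    ip, _ = linkage.deduplicate_records(ip)
    pairs, under, ledger = linkage.apply_inclusion_exclusion(ed, ip, clean_directory)
    return pairs, under, ledger


@pytest.fixture(scope="session")
def clean_events(clean_cohort, clean_directory):
    pairs, _, _ = clean_cohort
    return cohort.encode_covariates(cohort.label_optimality(pairs, clean_directory))


def make_directory(records=None):
    """Tiny hand-built directory for targeted unit tests."""
    if records is None:
        records = [
            dict(facility_id="A", level="NONTRAUMA", lat=34.0, lon=-118.0),
            dict(facility_id="B", level="LEVEL_II", lat=34.1, lon=-118.1),
            dict(facility_id="C", level="LEVEL_III", lat=34.2, lon=-118.2),
            dict(facility_id="D", level="LEVEL_I", lat=37.7, lon=-122.4),
            dict(facility_id="E", level="LEVEL_IV", lat=34.3, lon=-118.3),
            dict(facility_id="R", level="NONTRAUMA", lat=34.4, lon=-118.4,
                 facility_type="REHAB"),
        ]
    full = []
    for r in records:
        full.append(
            {
                "facility_id": r["facility_id"],
                "name": r["facility_id"],
                "latitude": r.get("lat", 34.0),
                "longitude": r.get("lon", -118.0),
                "facility_type": r.get("facility_type", "SHORT_TERM_ACUTE"),
                "lemsa_id": r.get("lemsa_id", "L1"),
                "rtcc_id": r.get("rtcc_id", "SOUTH_WEST"),
                "level_by_year": {y: r["level"] for y in range(2009, 2019)},
            }
        )
    return HospitalDirectory.from_records(full)


ENCOUNTER_DEFAULTS = dict(
    rln="P1",
    facility_id="A",
    record_kind="ED",
    admit_date=dt.date(2018, 5, 1),
    discharge_date=dt.date(2018, 5, 1),
    disposition="acute-transfer",
    admission_type="EMERGENT",
    age=40,
    sex="MALE",
    race="white",
    ethnicity="non-hispanic",
    insurance="medicare",
    riss=20,
    mechanism="fall",
    body_region="TBI",
    burn_flag=False,
    year=2018,
)


def make_encounters(rows):
    """Encounter frame from partial dicts, filling defaults."""
    if not rows:
        return pd.DataFrame(columns=list(ENCOUNTER_DEFAULTS))
    return pd.DataFrame([{**ENCOUNTER_DEFAULTS, **r} for r in rows])
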