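import datetime as dt
import logging
from pathlib import Path

import pytest

from fiska import cohort, fuzzy, scoring
from fiska.core import DonorRecord, PatientRecord

FIXTURES = Path(__file__).resolve().parent.parent / "fixtures"

HLA_SELF = {"A": ("A1", "A2"), "B": ("B1", "B2"), "DR": ("DR1", "DR2")}
HLA_OTHER = {"A": ("A3", "A4"), "B": ("B3", "B4"), "DR": ("DR3", "DR4")}


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    caplog.set_level(logging.ERROR)


@pytest.fixture(scope="session")
def weights():
    return scoring.load_weight_table()


@pytest.fixture(scope="session")
def default_variables():
    return fuzzy.load_default_variables()


@pytest.fixture(scope="session")
def fixtures_dir():
    return FIXTURES


@pytest.fixture
def make_patient():
    def _make(**kwargs):
        base = dict(
            patient_id="P1",
            recipient_age=40.0,
            blood_type="O",
            pra=0.0,
            medical_urgency=0,
            hla_typing=HLA_SELF,
            predicted_survival=8.0,
            diabetes=0,
            prior_solid_organ_transplant=0,
            dialysis_years=1.0,
            waiting_time_years=1.0,
        )
        base.update(kwargs)
        return PatientRecord(**base)

    return _make


@pytest.fixture
def make_donor():
    def _make(**kwargs):
        base = dict(
            donor_id="D1",
            donor_age=40.0,
            blood_type="O",
            hla_typing=HLA_SELF,
            allocation_date=dt.date(2018, 1, 1),
        )
        base.update(kwargs)
        return DonorRecord(**base)

    return _make


@pytest.fixture(scope="session")
def labeled_table_5000():
    """Seeded 5000-patient labeled training table shared by the slow tests."""
    config = cohort.CohortConfig(n_patients=5000, n_donors=100, seed=7)
    return cohort.generate_labeled_dataset(config)
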