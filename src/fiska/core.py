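"""Domain records and clinical compatibility computations.

Everything downstream (point scoring, fuzzy ranking, filtering) consumes the
four primitives defined here: the ABO donor/recipient relation, the HLA
mismatch count over loci A/B/DR, waiting time in years, and the donor-recipient
age difference.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .errors import InputError, SchemaError

BLOOD_TYPES = ("A", "B", "AB", "O")
HLA_LOCI = ("A", "B", "DR")

#: recipient blood types each donor type may donate to (standard ABO rules)
_ABO_RECIPIENTS = {
    "O": {"O", "A", "B", "AB"},
    "A": {"A", "AB"},
    "B": {"B", "AB"},
    "AB": {"AB"},
}

DAYS_PER_YEAR = 365.25

HlaTyping = Mapping[str, Sequence[str]]


class AboRelation(str, Enum):
    """Donor-to-recipient blood-group relation."""

    IDENTICAL = "identical"
    COMPATIBLE = "compatible"
    INCOMPATIBLE = "incompatible"


def _check_blood_type(value: str, role: str) -> str:
    if value not in BLOOD_TYPES:
        raise InputError(f"unknown {role} blood type {value!r}; expected one of {BLOOD_TYPES}")
    return value


def _check_hla(typing: HlaTyping, owner: str) -> dict[str, tuple[str, str]]:
    if typing is None:
        raise InputError(f"{owner}: missing HLA typing")
    out = {}
    for locus in HLA_LOCI:
        if locus not in typing:
            raise InputError(f"{owner}: missing HLA locus {locus!r}")
        antigens = tuple(str(a) for a in typing[locus])
        if len(antigens) != 2:
            raise InputError(
                f"{owner}: locus {locus!r} must carry exactly 2 antigen labels, got {antigens!r}"
            )
        out[locus] = antigens
    return out


def _check_binary(value, name: str, owner: str) -> int:
    iv = int(value)
    if iv not in (0, 1):
        raise InputError(f"{owner}: {name} must be 0 or 1, got {value!r}")
    return iv


@dataclass
class PatientRecord:
    """One waiting-list candidate with every attribute any ranking method needs.

    ``waiting_time_years``, when given, overrides date arithmetic so cohorts
    without listing dates are still usable; otherwise ``listing_date`` is
    required.
    """

    patient_id: str
    recipient_age: float
    blood_type: str
    pra: float
    medical_urgency: int
    hla_typing: HlaTyping
    predicted_survival: float
    diabetes: int = 0
    prior_solid_organ_transplant: int = 0
    dialysis_years: float = 0.0
    listing_date: _dt.date | None = None
    waiting_time_years: float | None = None

    def __post_init__(self):
        who = f"patient {self.patient_id!r}"
        self.patient_id = str(self.patient_id)
        if not 0 <= self.recipient_age <= 120:
            raise InputError(f"{who}: recipient_age {self.recipient_age} outside [0, 120]")
        _check_blood_type(self.blood_type, "recipient")
        if not 0 <= self.pra <= 100:
            raise InputError(f"{who}: pra {self.pra} outside [0, 100]")
        self.medical_urgency = _check_binary(self.medical_urgency, "medical_urgency", who)
        self.diabetes = _check_binary(self.diabetes, "diabetes", who)
        self.prior_solid_organ_transplant = _check_binary(
            self.prior_solid_organ_transplant, "prior_solid_organ_transplant", who
        )
        self.hla_typing = _check_hla(self.hla_typing, who)
        if self.predicted_survival < 0:
            raise InputError(f"{who}: predicted_survival must be >= 0")
        if self.dialysis_years < 0:
            raise InputError(f"{who}: dialysis_years must be >= 0")
        if self.listing_date is None and self.waiting_time_years is None:
            raise InputError(f"{who}: needs listing_date or waiting_time_years")
        if self.waiting_time_years is not None and self.waiting_time_years < 0:
            raise InputError(f"{who}: waiting_time_years must be >= 0")


@dataclass
class DonorRecord:
    """One deceased donor offered to the waiting list."""

    donor_id: str
    donor_age: float
    blood_type: str
    hla_typing: HlaTyping
    allocation_date: _dt.date

    def __post_init__(self):
        who = f"donor {self.donor_id!r}"
        self.donor_id = str(self.donor_id)
        if self.donor_age < 0:
            raise InputError(f"{who}: donor_age must be >= 0")
        _check_blood_type(self.blood_type, "donor")
        self.hla_typing = _check_hla(self.hla_typing, who)
        if not isinstance(self.allocation_date, _dt.date):
            raise InputError(f"{who}: allocation_date must be a date")


def abo_relation(donor_bt: str, recipient_bt: str) -> AboRelation:
    """Classify the donor→recipient blood-group relation.

    ``identical`` when equal; ``compatible`` when the donor may donate to the
    recipient under standard ABO rules (O→all, A→{A,AB}, B→{B,AB}, AB→{AB});
    ``incompatible`` otherwise.
    """
    _check_blood_type(donor_bt, "donor")
    _check_blood_type(recipient_bt, "recipient")
    if donor_bt == recipient_bt:
        return AboRelation.IDENTICAL
    if recipient_bt in _ABO_RECIPIENTS[donor_bt]:
        return AboRelation.COMPATIBLE
    return AboRelation.INCOMPATIBLE


def count_hla_mismatches(donor_hla: HlaTyping, recipient_hla: HlaTyping) -> int:
    """Count donor antigens absent from the recipient, over loci A, B, DR.

    Each distinct donor antigen at a locus counts once (a homozygous donor
    contributes a single distinct antigen), giving a count in 0..6.
    """
    d = _check_hla(donor_hla, "donor")
    r = _check_hla(recipient_hla, "recipient")
    return sum(len(set(d[locus]) - set(r[locus])) for locus in HLA_LOCI)


def waiting_time_years(listing_date: _dt.date, allocation_date: _dt.date) -> float:
    """Elapsed time from listing to allocation, in 365.25-day years."""
    if listing_date > allocation_date:
        raise InputError(
            f"listing_date {listing_date} is after allocation_date {allocation_date}"
        )
    return (allocation_date - listing_date).days / DAYS_PER_YEAR


def age_difference(donor_age: float, recipient_age: float) -> float:
    """Absolute donor-recipient age difference in years."""
    if donor_age < 0 or recipient_age < 0:
        raise InputError("ages must be >= 0")
    return abs(donor_age - recipient_age)


def patient_waiting_time(patient: PatientRecord, donor: DonorRecord) -> float:
    """Waiting time for one patient at a donor's allocation date.

    Uses the explicit ``waiting_time_years`` override when present, otherwise
    date arithmetic.
    """
    if patient.waiting_time_years is not None:
        return float(patient.waiting_time_years)
    return waiting_time_years(patient.listing_date, donor.allocation_date)


# ---------------------------------------------------------------------------
# CSV input/output (waiting-list and donor schemas)
# ---------------------------------------------------------------------------

_HLA_COLUMNS = ["hla_a1", "hla_a2", "hla_b1", "hla_b2", "hla_dr1", "hla_dr2"]

WAITLIST_COLUMNS = [
    "patient_id", "recipient_age", "blood_type", "pra", "medical_urgency",
    *_HLA_COLUMNS, "predicted_survival", "diabetes",
    "prior_solid_organ_transplant", "dialysis_years",
]
DONOR_COLUMNS = ["donor_id", "donor_age", "blood_type", *_HLA_COLUMNS, "allocation_date"]


def _hla_from_row(row) -> dict[str, tuple[str, str]]:
    return {
        "A": (row["hla_a1"], row["hla_a2"]),
        "B": (row["hla_b1"], row["hla_b2"]),
        "DR": (row["hla_dr1"], row["hla_dr2"]),
    }


def _hla_to_row(typing: HlaTyping) -> dict[str, str]:
    return {
        "hla_a1": typing["A"][0], "hla_a2": typing["A"][1],
        "hla_b1": typing["B"][0], "hla_b2": typing["B"][1],
        "hla_dr1": typing["DR"][0], "hla_dr2": typing["DR"][1],
    }


def _parse_date(value) -> _dt.date:
    try:
        return _dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise InputError(f"cannot parse ISO date from {value!r}") from exc


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def read_waitlist(path) -> list[PatientRecord]:
    """Load a waiting-list CSV into validated :class:`PatientRecord` objects."""
    df = pd.read_csv(path, dtype={"patient_id": str, **{c: str for c in _HLA_COLUMNS}})
    _require_columns(df, WAITLIST_COLUMNS, "waiting list")
    has_dates = "listing_date" in df.columns
    has_wt = "waiting_time_years" in df.columns
    if not has_dates and not has_wt:
        raise SchemaError("waiting list: needs a listing_date or waiting_time_years column")
    patients = []
    for _, row in df.iterrows():
        listing = None
        wt = None
        if has_dates and pd.notna(row.get("listing_date")):
            listing = _parse_date(row["listing_date"])
        if has_wt and pd.notna(row.get("waiting_time_years")):
            wt = float(row["waiting_time_years"])
        patients.append(PatientRecord(
            patient_id=row["patient_id"],
            recipient_age=float(row["recipient_age"]),
            blood_type=str(row["blood_type"]),
            pra=float(row["pra"]),
            medical_urgency=int(row["medical_urgency"]),
            hla_typing=_hla_from_row(row),
            predicted_survival=float(row["predicted_survival"]),
            diabetes=int(row["diabetes"]),
            prior_solid_organ_transplant=int(row["prior_solid_organ_transplant"]),
            dialysis_years=float(row["dialysis_years"]),
            listing_date=listing,
            waiting_time_years=wt,
        ))
    return patients


def read_donors(path) -> list[DonorRecord]:
    """Load a donor CSV into validated :class:`DonorRecord` objects."""
    df = pd.read_csv(path, dtype={"donor_id": str, **{c: str for c in _HLA_COLUMNS}})
    _require_columns(df, DONOR_COLUMNS, "donor table")
    return [
        DonorRecord(
            donor_id=row["donor_id"],
            donor_age=float(row["donor_age"]),
            blood_type=str(row["blood_type"]),
            hla_typing=_hla_from_row(row),
            allocation_date=_parse_date(row["allocation_date"]),
        )
        for _, row in df.iterrows()
    ]


def write_waitlist(patients: Sequence[PatientRecord], path) -> None:
    rows = []
    for p in patients:
        row = {
            "patient_id": p.patient_id,
            "recipient_age": p.recipient_age,
            "blood_type": p.blood_type,
            "pra": p.pra,
            "medical_urgency": p.medical_urgency,
            **_hla_to_row(p.hla_typing),
            "predicted_survival": p.predicted_survival,
            "diabetes": p.diabetes,
            "prior_solid_organ_transplant": p.prior_solid_organ_transplant,
            "dialysis_years": p.dialysis_years,
        }
        if p.listing_date is not None:
            row["listing_date"] = p.listing_date.isoformat()
        if p.waiting_time_years is not None:
            row["waiting_time_years"] = p.waiting_time_years
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_donors(donors: Sequence[DonorRecord], path) -> None:
    rows = [
        {
            "donor_id": d.donor_id,
            "donor_age": d.donor_age,
            "blood_type": d.blood_type,
            **_hla_to_row(d.hla_typing),
            "allocation_date": d.allocation_date.isoformat(),
        }
        for d in donors
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
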