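"""Ranking policies (fuzzy, point-scoring, filtering) and evaluation metrics:
top-k overlap, two-first-choices agreement, the raw post-transplant survival
score, and per-method outcome summaries.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import core, fuzzy, scoring
from .core import AboRelation, DonorRecord, PatientRecord
from .errors import InputError
from .fuzzy import RuleBase
from .induction import pair_features
from .scoring import WeightTable

logger = logging.getLogger(__name__)

TOP_K = 6
N_RECIPIENTS = 2


@dataclass(frozen=True)
class RankEntry:
    rank: int
    patient_id: str
    score: float | None = None


@dataclass
class RankedList:
    """Ordered allocation priorities for one donor under one method.

    The first two entries are the kidney recipients; the next four are
    reserves.
    """

    method: str
    entries: list[RankEntry]

    def __post_init__(self):
        for i, entry in enumerate(self.entries, start=1):
            if entry.rank != i:
                raise InputError(f"ranks must be contiguous from 1; entry {i} has rank {entry.rank}")

    @property
    def patient_ids(self) -> list[str]:
        return [e.patient_id for e in self.entries]

    def top(self, k: int = TOP_K) -> list[str]:
        return self.patient_ids[:k]

    @property
    def recipients(self) -> list[str]:
        return self.patient_ids[:N_RECIPIENTS]

    @property
    def reserves(self) -> list[str]:
        return self.patient_ids[N_RECIPIENTS:TOP_K]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"method": self.method, "rank": e.rank, "patient_id": e.patient_id,
              "score": e.score} for e in self.entries]
        )


def compatible_patients(
    waitlist: Sequence[PatientRecord], donor: DonorRecord
) -> list[PatientRecord]:
    """The ABO-compatible subset, preserving input order; exclusions logged.

    All ranking policies share this filter, so every method excludes exactly
    the same patients.
    """
    kept = []
    for p in waitlist:
        if core.abo_relation(donor.blood_type, p.blood_type) is AboRelation.INCOMPATIBLE:
            logger.info("excluding patient %s: ABO incompatible with donor %s",
                        p.patient_id, donor.donor_id)
        else:
            kept.append(p)
    return kept


def _ranked(method: str, scored: list[tuple[PatientRecord, float]],
            donor: DonorRecord) -> RankedList:
    # descending score; ties broken by longer waiting time, then patient_id
    scored.sort(key=lambda pw: (-pw[1], -core.patient_waiting_time(pw[0], donor),
                                pw[0].patient_id))
    entries = [RankEntry(i, p.patient_id, s) for i, (p, s) in enumerate(scored, start=1)]
    return RankedList(method, entries)


def rank_fiska(
    waitlist: Sequence[PatientRecord],
    donor: DonorRecord,
    rulebase: RuleBase,
    resolution: float = fuzzy.DEFAULT_RESOLUTION,
    fallback: str | None = None,
) -> RankedList:
    """Rank compatible patients by the fuzzy system's crisp priority score.

    ``fallback`` (an output-set name) scores patients the rule base does not
    cover at that set's centroid instead of raising
    :class:`~fiska.errors.NoRuleFiredError`.
    """
    patients = compatible_patients(waitlist, donor)
    if not patients:
        logger.warning("no ABO-compatible patients for donor %s", donor.donor_id)
        return RankedList("fiska", [])
    scored = [
        (p, fuzzy.infer(pair_features(p, donor), rulebase, resolution, fallback))
        for p in patients
    ]
    return _ranked("fiska", scored, donor)


def rank_scoring(
    waitlist: Sequence[PatientRecord], donor: DonorRecord, weights: WeightTable
) -> RankedList:
    """Rank compatible patients by weighted total points."""
    patients = compatible_patients(waitlist, donor)
    if not patients:
        logger.warning("no ABO-compatible patients for donor %s", donor.donor_id)
        return RankedList("scoring", [])
    scored = [(p, scoring.total_score(p, donor, weights)) for p in patients]
    return _ranked("scoring", scored, donor)


def rank_filtering(
    waitlist: Sequence[PatientRecord],
    donor: DonorRecord,
    urgent_only: bool = False,
    top_k: int = TOP_K,
) -> RankedList:
    """Baseline filter: ABO-compatible, urgency tier first, waiting time
    descending within tier, truncated to ``top_k``.

    ``urgent_only=True`` switches to a hard urgency filter that discards
    non-urgent patients instead of tiering them.
    """
    patients = compatible_patients(waitlist, donor)
    if urgent_only:
        patients = [p for p in patients if p.medical_urgency]
    ordered = sorted(
        patients,
        key=lambda p: (-p.medical_urgency, -core.patient_waiting_time(p, donor),
                       p.patient_id),
    )[:top_k]
    entries = [RankEntry(i, p.patient_id, None) for i, p in enumerate(ordered, start=1)]
    return RankedList("filtering", entries)


# ---------------------------------------------------------------------------
# Agreement metrics
# ---------------------------------------------------------------------------

def _truncate_1dp(value: float) -> float:
    return math.floor(value * 10.0) / 10.0


def _check_unique(ids: Sequence[str], which: str, k: int) -> set[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise InputError(f"{which} list contains duplicate ids: {ids}")
    if len(ids) > k:
        raise InputError(f"{which} list has {len(ids)} ids, more than k={k}")
    return set(ids)


def overlapping_rate(list_a: Sequence[str], list_b: Sequence[str], k: int = TOP_K) -> float:
    """Percent of shared candidates among two top-k lists, truncated to one
    decimal (4 of 6 -> 66.6)."""
    a = _check_unique(list_a, "first", k)
    b = _check_unique(list_b, "second", k)
    return _truncate_1dp(100.0 * len(a & b) / k)


def two_first_choices(list_a: Sequence[str], list_b: Sequence[str]) -> float:
    """Percent agreement of the unordered top-2 selections: 100, 50, or 0."""
    if len(list_a) < 2 or len(list_b) < 2:
        raise InputError("both lists need at least 2 entries")
    a = {str(i) for i in list_a[:2]}
    b = {str(i) for i in list_b[:2]}
    return 100.0 * len(a & b) / 2.0


# ---------------------------------------------------------------------------
# Post-transplant survival score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EptsInput:
    """Covariates of the raw post-transplant survival score."""

    age: float
    diabetes: int
    prior_solid_organ_transplant: int
    dialysis_years: float

    def __post_init__(self):
        if self.diabetes not in (0, 1) or self.prior_solid_organ_transplant not in (0, 1):
            raise InputError("diabetes and prior_solid_organ_transplant must be 0 or 1")
        if self.dialysis_years < 0:
            raise InputError("dialysis_years must be >= 0")
        if self.age < 0:
            raise InputError("age must be >= 0")

    @classmethod
    def from_patient(cls, patient: PatientRecord) -> "EptsInput":
        return cls(
            age=patient.recipient_age,
            diabetes=patient.diabetes,
            prior_solid_organ_transplant=patient.prior_solid_organ_transplant,
            dialysis_years=patient.dialysis_years,
        )


def epts_raw(inputs: EptsInput) -> float:
    """Raw survival score: age above 25, prior transplant, log dialysis years,
    and diabetes interactions, with natural logs and 0/1 indicators.

    Lower is better (longer expected graft benefit). Returned unconverted;
    percentile mapping needs an external table.
    """
    age_excess = max(inputs.age - 25.0, 0.0)
    dia = float(inputs.diabetes)
    prior = float(inputs.prior_solid_organ_transplant)
    log_dialysis = math.log(inputs.dialysis_years + 1.0)
    no_dialysis = 1.0 if inputs.dialysis_years == 0 else 0.0
    return (
        0.047 * age_excess
        - 0.015 * dia * age_excess
        + 0.398 * prior
        - 0.237 * dia * prior
        + 0.315 * log_dialysis
        - 0.099 * dia * log_dialysis
        + 0.130 * no_dialysis
        - 0.348 * dia * no_dialysis
        + 1.262 * dia
    )


def apply_percentile_table(raw: float, table: pd.DataFrame) -> float:
    """Map a raw score to a percentile via a user-supplied two-column table
    (``raw``, ``percentile``), using the largest tabulated raw <= score."""
    if not {"raw", "percentile"} <= set(table.columns):
        raise InputError("percentile table needs 'raw' and 'percentile' columns")
    table = table.sort_values("raw")
    eligible = table[table["raw"] <= raw]
    row = eligible.iloc[-1] if len(eligible) else table.iloc[0]
    return float(row["percentile"])


# ---------------------------------------------------------------------------
# Outcome comparison
# ---------------------------------------------------------------------------

@dataclass
class OutcomeReport:
    """Per-method means of the factors that proxy transplant outcome."""

    table: pd.DataFrame  # one row per method

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def compare_outcomes(
    allocations: Mapping[str, Sequence[tuple[str, str]]],
    patients: Sequence[PatientRecord],
    donors: Sequence[DonorRecord],
) -> OutcomeReport:
    """Summarize chosen recipients per method.

    ``allocations`` maps method name to (patient_id, donor_id) pairs — the
    recorded recipients of each donor run.
    """
    patient_by_id = {p.patient_id: p for p in patients}
    donor_by_id = {d.donor_id: d for d in donors}
    rows = []
    for method, chosen in allocations.items():
        if not chosen:
            raise InputError(f"method {method!r} has no recorded allocations")
        epts_vals, waits, diffs, identical = [], [], [], 0
        for pid, did in chosen:
            try:
                patient = patient_by_id[pid]
                donor = donor_by_id[did]
            except KeyError as exc:
                raise InputError(f"method {method!r}: unknown id {exc.args[0]!r}")
            epts_vals.append(epts_raw(EptsInput.from_patient(patient)))
            waits.append(core.patient_waiting_time(patient, donor))
            diffs.append(core.age_difference(donor.donor_age, patient.recipient_age))
            if core.abo_relation(donor.blood_type, patient.blood_type) is AboRelation.IDENTICAL:
                identical += 1
        n = len(chosen)
        rows.append({
            "method": method,
            "n_allocations": n,
            "mean_epts_raw": sum(epts_vals) / n,
            "mean_waiting_time_years": sum(waits) / n,
            "mean_age_difference_years": sum(diffs) / n,
            "identical_abo_count": identical,
            "identical_abo_fraction": identical / n,
        })
    return OutcomeReport(pd.DataFrame(rows))
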