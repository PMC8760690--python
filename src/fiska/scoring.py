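"""Point-scoring allocation: weighted total score and 5-class quantization.

The weight table has three levels — criterion (equity/utility), sub-criterion,
and, for binned sub-criteria, attribute bin. A patient's total score is 100x
the sum of the applicable global weights; waiting time accrues points linearly
per year, uncapped.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import core
from .core import AboRelation, DonorRecord, PatientRecord
from .errors import ConfigError, DomainError

#: sub-criteria whose points depend on an attribute bin, with the bins each
#: config document must supply
_BINNED = {
    "recipient_age": ("under_11", "age_11_15", "age_15_18"),
    "hla_mismatching": ("mm0", "mm1", "mm2", "mm3", "mm4", "mm5"),
    "blood_type_matching": ("identical", "compatible"),
    "age_difference": ("under_5", "diff_5_15", "over_15"),
    "predicted_survival": ("under_1", "surv_1_5", "over_5"),
}
_FLAT = ("medical_urgency", "pra_over_80", "waiting_time_per_year")

CRITERION_SUM_TOL = 0.01
GROUP_SUM_TOL = 0.02
PRODUCT_TOL = 2e-4


class PriorityClass(IntEnum):
    """Ordered five-level priority label."""

    VERY_LOW = 0
    LOW = 1
    MEDIUM = 2
    HIGH = 3
    VERY_HIGH = 4

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "PriorityClass":
        return cls[label.upper()]


PRIORITY_LABELS = tuple(c.label for c in PriorityClass)


@dataclass(frozen=True)
class WeightTable:
    """Validated allocation weights.

    ``global_weights`` maps flat sub-criterion names and ``sub:bin`` keys to
    their global weight; the relative-weight structure is kept for the
    consistency checks and for reporting.
    """

    criterion_weights: Mapping[str, float]
    sub_weights: Mapping[str, Mapping[str, float]]
    bin_weights: Mapping[str, Mapping[str, float]]
    global_weights: Mapping[str, float]

    def weight(self, sub: str, bin_name: str | None = None) -> float:
        key = sub if bin_name is None else f"{sub}:{bin_name}"
        return self.global_weights[key]


def _validate(criterion_weights, sub_weights, bin_weights, global_weights) -> list[str]:
    problems = []
    crit_sum = sum(criterion_weights.values())
    if abs(crit_sum - 1.0) > CRITERION_SUM_TOL:
        problems.append(f"criterion weights sum to {crit_sum:.4f}, expected 1 +/- {CRITERION_SUM_TOL}")
    for crit, subs in sub_weights.items():
        s = sum(subs.values())
        if abs(s - 1.0) > GROUP_SUM_TOL:
            problems.append(f"{crit} sub-criterion weights sum to {s:.4f}, expected 1 +/- {GROUP_SUM_TOL}")
    for sub, bins in bin_weights.items():
        s = sum(bins.values())
        if abs(s - 1.0) > GROUP_SUM_TOL:
            problems.append(f"{sub} bin weights sum to {s:.4f}, expected 1 +/- {GROUP_SUM_TOL}")
    # product consistency: global == criterion * sub (* bin)
    sub_to_crit = {sub: crit for crit, subs in sub_weights.items() for sub in subs}
    for key, gw in global_weights.items():
        sub, _, bin_name = key.partition(":")
        crit = sub_to_crit[sub]
        product = criterion_weights[crit] * sub_weights[crit][sub]
        if bin_name:
            product *= bin_weights[sub][bin_name]
        if abs(product - gw) > PRODUCT_TOL:
            problems.append(
                f"{key}: global weight {gw} differs from product {product:.5f} "
                f"by more than {PRODUCT_TOL}"
            )
    return problems


def load_weight_table(config=None) -> WeightTable:
    """Build a :class:`WeightTable` from a config mapping, YAML path, or the
    packaged default (when ``config`` is None).

    Raises :class:`ConfigError` listing every missing entry or failed
    invariant.
    """
    if config is None:
        ref = importlib.resources.files("fiska.data") / "table2_weights.yaml"
        doc = yaml.safe_load(ref.read_text())
    elif isinstance(config, Mapping):
        doc = config
    else:
        with open(config) as fh:
            doc = yaml.safe_load(fh)

    try:
        criteria = doc["criteria"]
    except (KeyError, TypeError):
        raise ConfigError("weight config: missing top-level 'criteria' mapping")

    criterion_weights: dict[str, float] = {}
    sub_weights: dict[str, dict[str, float]] = {}
    bin_weights: dict[str, dict[str, float]] = {}
    global_weights: dict[str, float] = {}
    problems: list[str] = []

    for crit, spec in criteria.items():
        criterion_weights[crit] = float(spec["weight"])
        sub_weights[crit] = {}
        for sub, sub_spec in spec.get("sub_criteria", {}).items():
            sub_weights[crit][sub] = float(sub_spec["weight"])
            if "bins" in sub_spec:
                bin_weights[sub] = {}
                for bin_name, bin_spec in sub_spec["bins"].items():
                    bin_weights[sub][bin_name] = float(bin_spec["weight"])
                    global_weights[f"{sub}:{bin_name}"] = float(bin_spec["global"])
            else:
                global_weights[sub] = float(sub_spec["global"])

    for sub in _FLAT:
        if sub not in global_weights:
            problems.append(f"missing flat sub-criterion {sub!r}")
    for sub, bins in _BINNED.items():
        for b in bins:
            if f"{sub}:{b}" not in global_weights:
                problems.append(f"missing bin {sub}:{b}")

    if not problems:
        problems = _validate(criterion_weights, sub_weights, bin_weights, global_weights)
    if problems:
        raise ConfigError("invalid weight config:\n  " + "\n  ".join(problems))
    return WeightTable(criterion_weights, sub_weights, bin_weights, global_weights)


# ---------------------------------------------------------------------------
# Bin selection
# ---------------------------------------------------------------------------

def hla_bin(mismatches: int) -> str:
    # counts of 6 (possible over 3 loci x 2 antigens) collapse to the 5-mismatch bin
    return f"mm{min(int(mismatches), 5)}"


def recipient_age_bin(age: float) -> str | None:
    """Pediatric age bin, or None for adults (>= 18), who score no age points."""
    if age < 11:
        return "under_11"
    if age < 15:
        return "age_11_15"
    if age < 18:
        return "age_15_18"
    return None


def age_difference_bin(diff: float) -> str:
    if diff < 5:
        return "under_5"
    if diff <= 15:
        return "diff_5_15"
    return "over_15"


def survival_bin(years: float) -> str:
    if years < 1:
        return "under_1"
    if years <= 5:
        return "surv_1_5"
    return "over_5"


def abo_bin(relation: AboRelation) -> str:
    if relation is AboRelation.INCOMPATIBLE:
        raise DomainError("ABO-incompatible pair has no blood-type-matching bin")
    return relation.value


PRA_THRESHOLD = 80.0


def total_score(patient: PatientRecord, donor: DonorRecord, weights: WeightTable) -> float:
    """Total allocation score on a 0-100 scale (sum of global weights x 100).

    The pair must be ABO-compatible; incompatible patients are filtered before
    scoring and raise :class:`DomainError` here.
    """
    relation = core.abo_relation(donor.blood_type, patient.blood_type)
    if relation is AboRelation.INCOMPATIBLE:
        raise DomainError(
            f"patient {patient.patient_id!r} is ABO-incompatible with donor "
            f"{donor.donor_id!r}; pre-filter the waiting list"
        )
    total = 0.0
    if patient.medical_urgency:
        total += weights.weight("medical_urgency")
    if patient.pra > PRA_THRESHOLD:
        total += weights.weight("pra_over_80")
    age_b = recipient_age_bin(patient.recipient_age)
    if age_b is not None:
        total += weights.weight("recipient_age", age_b)
    total += weights.weight("waiting_time_per_year") * core.patient_waiting_time(patient, donor)
    mm = core.count_hla_mismatches(donor.hla_typing, patient.hla_typing)
    total += weights.weight("hla_mismatching", hla_bin(mm))
    total += weights.weight("blood_type_matching", abo_bin(relation))
    diff = core.age_difference(donor.donor_age, patient.recipient_age)
    total += weights.weight("age_difference", age_difference_bin(diff))
    total += weights.weight("predicted_survival", survival_bin(patient.predicted_survival))
    return 100.0 * total


def quantize_priority(
    scores: Sequence[float], thresholds: Sequence[float] | None = None
) -> list[PriorityClass]:
    """Map scores to the five ordered priority classes.

    With explicit ``thresholds`` (4 strictly ascending cut points) classes are
    closed on the left and open on the right. Without thresholds, quintile cut
    points are computed from ``scores`` (requires >= 5 scores); when all scores
    tie the quantiles coincide and every score lands in a single class.
    """
    scores = np.asarray(scores, dtype=float)
    if thresholds is None:
        if scores.size < 5:
            raise ConfigError("quantile mode needs at least 5 scores")
        thresholds = np.quantile(scores, [0.2, 0.4, 0.6, 0.8])
    else:
        thresholds = np.asarray(thresholds, dtype=float)
        if thresholds.shape != (4,):
            raise ConfigError("need exactly 4 class thresholds")
        if not np.all(np.diff(thresholds) > 0):
            raise ConfigError(f"thresholds must be strictly ascending, got {thresholds.tolist()}")
    idx = np.searchsorted(thresholds, scores, side="right")
    return [PriorityClass(i) for i in idx]


def quantile_thresholds(scores: Sequence[float]) -> np.ndarray:
    """The quintile cut points quantize_priority uses in quantile mode."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 5:
        raise ConfigError("quantile mode needs at least 5 scores")
    return np.quantile(scores, [0.2, 0.4, 0.6, 0.8])
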