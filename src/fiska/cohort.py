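"""Seeded synthetic patient/donor cohorts.

Stands in for registry extracts during development and testing. One global
seed fans out to named substreams (one per generated field), so adding a new
field later cannot perturb the draws of existing ones.

Default marginals are plausible but deliberately simple; no correctness test
depends on them beyond documented statistical tolerances.
"""
from __future__ import annotations

import datetime as _dt
import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import core
from .core import AboRelation, DonorRecord, PatientRecord
from .errors import ConfigError
from .induction import build_training_table
from .scoring import WeightTable, load_weight_table

logger = logging.getLogger(__name__)

REFERENCE_DATE = _dt.date(2018, 1, 1)

DEFAULT_BLOOD_TYPE_FREQS = {"O": 0.37, "A": 0.34, "B": 0.22, "AB": 0.07}
DEFAULT_HLA_POOL_SIZES = {"A": 10, "B": 15, "DR": 8}


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 100
    n_donors: int = 10
    seed: int = 0
    urgency_prevalence: float = 0.10
    diabetes_prevalence: float = 0.30
    prior_tx_prevalence: float = 0.10
    blood_type_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BLOOD_TYPE_FREQS))
    pra_zero_mass: float = 0.60
    age_mean: float = 45.0
    age_sd: float = 15.0
    age_min: float = 1.0
    age_max: float = 80.0
    waiting_scale_years: float = 2.0
    dialysis_scale_years: float = 3.0
    hla_pool_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_HLA_POOL_SIZES))

    def __post_init__(self):
        if self.n_patients < 1 or self.n_donors < 1:
            raise ConfigError("n_patients and n_donors must be >= 1")
        for name in ("urgency_prevalence", "diabetes_prevalence", "prior_tx_prevalence",
                     "pra_zero_mass"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        freq_sum = sum(self.blood_type_freqs.get(bt, 0.0) for bt in core.BLOOD_TYPES)
        if abs(freq_sum - 1.0) > 1e-9:
            raise ConfigError(f"blood-type frequencies sum to {freq_sum}, expected 1")
        if not self.age_min < self.age_max:
            raise ConfigError("age_min must be < age_max")
        for locus in core.HLA_LOCI:
            if self.hla_pool_sizes.get(locus, 0) < 1:
                raise ConfigError(f"HLA pool for locus {locus} must have >= 1 antigen")


def _stream(config: CohortConfig, name: str) -> np.random.Generator:
    # stable per-field substream: seed plus a CRC of the stream name
    return np.random.default_rng([config.seed, zlib.crc32(name.encode())])


def _truncated_normal(rng, mean, sd, lo, hi, n) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def _draw_blood_types(rng, freqs, n) -> list[str]:
    types = list(core.BLOOD_TYPES)
    p = np.array([freqs[t] for t in types])
    return [types[i] for i in rng.choice(len(types), size=n, p=p / p.sum())]


def _draw_hla(rng, pool_sizes, n) -> list[dict]:
    typings = []
    pools = {locus: [f"{locus}{i + 1}" for i in range(pool_sizes[locus])]
             for locus in core.HLA_LOCI}
    for _ in range(n):
        typings.append({
            locus: tuple(rng.choice(pools[locus], size=2, replace=True))
            for locus in core.HLA_LOCI
        })
    return typings


def generate_patients(config: CohortConfig) -> list[PatientRecord]:
    """Deterministic synthetic waiting list satisfying every record invariant."""
    n = config.n_patients
    ages = _truncated_normal(_stream(config, "patient_age"), config.age_mean,
                             config.age_sd, config.age_min, config.age_max, n)
    blood = _draw_blood_types(_stream(config, "patient_blood"),
                              config.blood_type_freqs, n)
    hla = _draw_hla(_stream(config, "patient_hla"), config.hla_pool_sizes, n)
    urgency = _stream(config, "urgency").random(n) < config.urgency_prevalence
    diabetes = _stream(config, "diabetes").random(n) < config.diabetes_prevalence
    prior_tx = _stream(config, "prior_tx").random(n) < config.prior_tx_prevalence

    pra_rng = _stream(config, "pra")
    pra = np.where(pra_rng.random(n) < config.pra_zero_mass, 0.0,
                   pra_rng.uniform(0.0, 100.0, size=n))
    waiting = np.minimum(_stream(config, "waiting").exponential(
        config.waiting_scale_years, size=n), 10.0)
    dialysis = np.minimum(_stream(config, "dialysis").exponential(
        config.dialysis_scale_years, size=n), 15.0)

    # survival declines with age and dialysis exposure so monotonicity and
    # rule-induction tests have real signal
    surv_noise = _stream(config, "survival").normal(0.0, 2.0, size=n)
    survival = np.clip(16.0 - 0.12 * ages - 0.4 * dialysis + surv_noise, 0.1, 20.0)

    patients = []
    for i in range(n):
        listing = REFERENCE_DATE - _dt.timedelta(days=round(float(waiting[i]) * 365.25))
        patients.append(PatientRecord(
            patient_id=f"P{i + 1:04d}",
            recipient_age=round(float(ages[i]), 1),
            blood_type=blood[i],
            pra=round(float(pra[i]), 1),
            medical_urgency=int(urgency[i]),
            hla_typing=hla[i],
            predicted_survival=round(float(survival[i]), 2),
            diabetes=int(diabetes[i]),
            prior_solid_organ_transplant=int(prior_tx[i]),
            dialysis_years=round(float(dialysis[i]), 2),
            listing_date=listing,
        ))
    return patients


def generate_donors(config: CohortConfig) -> list[DonorRecord]:
    """Deterministic synthetic donor pool."""
    n = config.n_donors
    ages = _truncated_normal(_stream(config, "donor_age"), config.age_mean,
                             config.age_sd, 10.0, 75.0, n)
    blood = _draw_blood_types(_stream(config, "donor_blood"),
                              config.blood_type_freqs, n)
    hla = _draw_hla(_stream(config, "donor_hla"), config.hla_pool_sizes, n)
    offsets = _stream(config, "allocation_date").integers(0, 90, size=n)
    return [
        DonorRecord(
            donor_id=f"D{i + 1:03d}",
            donor_age=round(float(ages[i]), 1),
            blood_type=blood[i],
            hla_typing=hla[i],
            allocation_date=REFERENCE_DATE + _dt.timedelta(days=int(offsets[i])),
        )
        for i in range(n)
    ]


def generate_labeled_dataset(
    config: CohortConfig,
    weights: WeightTable | None = None,
    thresholds: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Pair each patient with a seeded random ABO-compatible donor and build
    the score-labeled training table.

    Patients with no compatible donor in the pool are dropped with a log
    entry, so the row count is at most ``n_patients``.
    """
    if weights is None:
        weights = load_weight_table()
    patients = generate_patients(config)
    donors = generate_donors(config)
    rng = _stream(config, "pairing")
    pairs = []
    for patient in patients:
        compatible = [
            d for d in donors
            if core.abo_relation(d.blood_type, patient.blood_type) is not AboRelation.INCOMPATIBLE
        ]
        if not compatible:
            logger.info("dropping patient %s: no ABO-compatible donor in pool",
                        patient.patient_id)
            continue
        pairs.append((patient, compatible[int(rng.integers(len(compatible)))]))
    return build_training_table(pairs, weights, thresholds)
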