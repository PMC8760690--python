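"""Rule extraction: score-labeled training tables, decision-tree induction,
conversion of root-to-leaf paths into fuzzy rules, and k-fold evaluation.

The bespoke step is :func:`tree_to_fuzzy_rules`: each crisp threshold interval
accumulated along a path is mapped to the fuzzy set with the largest
membership integral over that interval.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from . import core, scoring
from .core import AboRelation, DonorRecord, PatientRecord
from .errors import ConfigError, InputError, MalformedTreeError, SchemaError
from .fuzzy import FuzzyRule, LinguisticVariable, RuleBase, load_default_variables
from .scoring import PriorityClass, WeightTable

logger = logging.getLogger(__name__)

#: predictor columns, aligned with the default linguistic-variable names
FEATURES = [
    "medical_urgency", "pra", "recipient_age", "age_difference",
    "hla_mismatch", "waiting_time", "predicted_survival", "abo_identical",
]
SCORE_COLUMN = "total_score"
CLASS_COLUMN = "priority_class"

DEFAULT_MAX_DEPTH = 6
DEFAULT_MIN_LEAF = 20
DEFAULT_CV_SEED = 42


def pair_features(patient: PatientRecord, donor: DonorRecord) -> dict[str, float]:
    """The 8 crisp predictor values for one patient-donor pairing."""
    relation = core.abo_relation(donor.blood_type, patient.blood_type)
    if relation is AboRelation.INCOMPATIBLE:
        raise InputError(
            f"patient {patient.patient_id!r} ABO-incompatible with donor {donor.donor_id!r}"
        )
    return {
        "medical_urgency": float(patient.medical_urgency),
        "pra": float(patient.pra),
        "recipient_age": float(patient.recipient_age),
        "age_difference": core.age_difference(donor.donor_age, patient.recipient_age),
        "hla_mismatch": float(min(core.count_hla_mismatches(donor.hla_typing, patient.hla_typing), 5)),
        "waiting_time": core.patient_waiting_time(patient, donor),
        "predicted_survival": float(patient.predicted_survival),
        "abo_identical": 1.0 if relation is AboRelation.IDENTICAL else 0.0,
    }


def build_training_table(
    pairs: Sequence[tuple[PatientRecord, DonorRecord]],
    weights: WeightTable,
    thresholds: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Predictors + total score + quantized priority class, one row per pairing.

    ABO-incompatible pairings are rejected with a logged reason rather than
    raising. Quantile class cut points are computed on this table's scores when
    ``thresholds`` is None.
    """
    rows = []
    for patient, donor in pairs:
        relation = core.abo_relation(donor.blood_type, patient.blood_type)
        if relation is AboRelation.INCOMPATIBLE:
            logger.info(
                "rejecting pairing %s/%s: ABO incompatible (%s -> %s)",
                patient.patient_id, donor.donor_id, donor.blood_type, patient.blood_type,
            )
            continue
        row = {"patient_id": patient.patient_id, "donor_id": donor.donor_id}
        row.update(pair_features(patient, donor))
        row[SCORE_COLUMN] = scoring.total_score(patient, donor, weights)
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        return pd.DataFrame(columns=["patient_id", "donor_id", *FEATURES, SCORE_COLUMN, CLASS_COLUMN])
    classes = scoring.quantize_priority(table[SCORE_COLUMN].to_numpy(), thresholds)
    table[CLASS_COLUMN] = [c.label for c in classes]
    return table


def validate_training_table(table: pd.DataFrame) -> None:
    missing = [c for c in (*FEATURES, CLASS_COLUMN) if c not in table.columns]
    if missing:
        raise SchemaError(f"training table: missing columns {missing}")
    if table[FEATURES].isna().any().any():
        bad = [c for c in FEATURES if table[c].isna().any()]
        raise SchemaError(f"training table: missing predictor values in {bad}")
    unknown = set(table[CLASS_COLUMN]) - set(scoring.PRIORITY_LABELS)
    if unknown:
        raise SchemaError(f"training table: unknown class labels {sorted(unknown)}")


@dataclass(frozen=True)
class Leaf:
    """One root-to-leaf path: per-feature (lo, hi] interval constraints plus
    the leaf's class tally."""

    intervals: Mapping[str, tuple[float, float]]
    majority_class: str
    n_samples: int
    class_counts: Mapping[str, int]


@dataclass
class TreeModel:
    """A fitted axis-aligned classification tree plus its leaf paths."""

    estimator: DecisionTreeClassifier
    feature_names: list[str]
    classes: list[str]

    @property
    def n_leaves(self) -> int:
        return int(self.estimator.get_n_leaves())

    @property
    def max_depth(self) -> int:
        return int(self.estimator.get_depth())

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(X[self.feature_names].to_numpy())

    def leaves(self) -> list[Leaf]:
        """Enumerate leaves with the threshold intervals along their paths."""
        tree = self.estimator.tree_
        out: list[Leaf] = []

        def walk(node: int, bounds: dict[str, tuple[float, float]]):
            if tree.children_left[node] == -1:  # leaf
                counts = tree.value[node][0]
                # tree.value holds per-class sample (weighted) counts
                tally = {cls: int(round(c)) for cls, c in zip(self.classes, counts)}
                majority = self.classes[int(np.argmax(counts))]
                out.append(Leaf(
                    intervals=dict(bounds),
                    majority_class=majority,
                    n_samples=int(tree.n_node_samples[node]),
                    class_counts=tally,
                ))
                return
            feat = self.feature_names[tree.feature[node]]
            thr = float(tree.threshold[node])
            lo, hi = bounds.get(feat, (-math.inf, math.inf))
            left = dict(bounds)
            left[feat] = (lo, min(hi, thr))
            walk(tree.children_left[node], left)
            right = dict(bounds)
            right[feat] = (max(lo, thr), hi)
            walk(tree.children_right[node], right)

        walk(0, {})
        return out


def fit_tree(
    table: pd.DataFrame,
    max_depth: int = DEFAULT_MAX_DEPTH,
    min_leaf: int = DEFAULT_MIN_LEAF,
) -> TreeModel:
    """Gini-impurity binary tree over the 8 predictors, depth/leaf constrained.

    Deterministic for a fixed table and parameters. A single-class table
    yields a degenerate one-leaf tree with a warning.
    """
    validate_training_table(table)
    if max_depth <= 0 or min_leaf <= 0:
        raise ConfigError("max_depth and min_leaf must be positive")
    y = table[CLASS_COLUMN].to_numpy()
    if len(np.unique(y)) < 2:
        logger.warning("training table has a single class; tree is a single leaf")
    est = DecisionTreeClassifier(
        criterion="gini", max_depth=max_depth, min_samples_leaf=min_leaf, random_state=0
    )
    est.fit(table[FEATURES].to_numpy(), y)
    return TreeModel(est, list(FEATURES), [str(c) for c in est.classes_])


def _overlap_integral(fset, lo: float, hi: float, n: int = 201) -> float:
    if hi <= lo:
        return 0.0
    xs = np.linspace(lo, hi, n)
    return float(np.trapezoid(fset.membership(xs), xs))


def _best_set(variable: LinguisticVariable, lo: float, hi: float) -> str:
    """Fuzzy set with maximal membership integral over [lo, hi] clipped to the
    universe; ties by plateau center nearest the interval midpoint, then by
    set order."""
    ulo, uhi = variable.universe
    clo, chi = max(lo, ulo), min(hi, uhi)
    if clo > chi:
        raise MalformedTreeError(
            f"variable {variable.name!r}: path interval ({lo}, {hi}] does not meet "
            f"universe [{ulo}, {uhi}]"
        )
    midpoint = 0.5 * (clo + chi)
    scored = []
    for order, fset in enumerate(variable.sets):
        integral = _overlap_integral(fset, clo, chi)
        scored.append((-integral, abs(fset.plateau_center - midpoint), order, fset.name))
    scored.sort()
    return scored[0][3]


def tree_to_fuzzy_rules(
    tree: TreeModel,
    variables: Sequence[LinguisticVariable] | None = None,
    output: LinguisticVariable | None = None,
) -> RuleBase:
    """One fuzzy rule per leaf; duplicate rules merged, contradictions resolved
    toward the more populous leaf."""
    if variables is None or output is None:
        default_inputs, default_output = load_default_variables()
        variables = default_inputs if variables is None else variables
        output = default_output if output is None else output
    by_name = {v.name: v for v in variables}

    candidates: dict[frozenset, tuple[FuzzyRule, int]] = {}
    for leaf in tree.leaves():
        antecedent = {}
        for feat, (lo, hi) in leaf.intervals.items():
            if feat not in by_name:
                raise MalformedTreeError(f"split variable {feat!r} has no fuzzy definition")
            antecedent[feat] = _best_set(by_name[feat], lo, hi)
        rule = FuzzyRule(antecedent, leaf.majority_class)
        key = frozenset(antecedent.items())
        if key in candidates:
            prev, prev_n = candidates[key]
            if prev.consequent == rule.consequent:
                candidates[key] = (prev, prev_n + leaf.n_samples)
            elif leaf.n_samples > prev_n:
                logger.warning(
                    "conflicting rules for antecedent %s: keeping %r (n=%d) over %r (n=%d)",
                    dict(antecedent), rule.consequent, leaf.n_samples,
                    prev.consequent, prev_n,
                )
                candidates[key] = (rule, leaf.n_samples)
            else:
                logger.warning(
                    "conflicting rules for antecedent %s: keeping %r (n=%d) over %r (n=%d)",
                    dict(antecedent), prev.consequent, prev_n,
                    rule.consequent, leaf.n_samples,
                )
        else:
            candidates[key] = (rule, leaf.n_samples)

    rules = [rule for rule, _ in candidates.values()]
    return RuleBase(inputs=list(variables), output=output, rules=rules)


@dataclass
class CvReport:
    """Fold-averaged one-vs-rest metrics per class, in percent.

    Metrics undefined in a fold (zero denominator) are excluded from that
    class's average; a class never defined at all reports NaN.
    """

    folds: int
    per_class: Mapping[str, Mapping[str, float]]  # label -> metric -> percent
    overall_accuracy: float

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {label: self.per_class[label] for label in scoring.PRIORITY_LABELS
             if label in self.per_class}
        )
        return frame.reindex(["sensitivity", "specificity", "precision"])


def _fold_metrics(y_true, y_pred, labels) -> dict[str, dict[str, float]]:
    out = {}
    for label in labels:
        tp = int(np.sum((y_pred == label) & (y_true == label)))
        fn = int(np.sum((y_pred != label) & (y_true == label)))
        fp = int(np.sum((y_pred == label) & (y_true != label)))
        tn = int(np.sum((y_pred != label) & (y_true != label)))
        out[label] = {
            "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else math.nan,
            "specificity": 100.0 * tn / (tn + fp) if tn + fp else math.nan,
            "precision": 100.0 * tp / (tp + fp) if tp + fp else math.nan,
        }
    return out


def cross_validate(
    table: pd.DataFrame,
    k: int = 10,
    max_depth: int = DEFAULT_MAX_DEPTH,
    min_leaf: int = DEFAULT_MIN_LEAF,
    seed: int = DEFAULT_CV_SEED,
) -> CvReport:
    """Seeded stratified k-fold evaluation of the induced tree."""
    validate_training_table(table)
    if k < 2:
        raise ConfigError("k must be >= 2")
    if len(table) < k:
        raise ConfigError(f"table has {len(table)} rows, fewer than k={k}")
    X = table[FEATURES].to_numpy()
    y = table[CLASS_COLUMN].to_numpy()
    labels = [l for l in scoring.PRIORITY_LABELS if l in set(y)]
    min_class = pd.Series(y).value_counts().min()
    if min_class < k:
        logger.warning(
            "smallest class has %d members for k=%d folds; some folds will miss it",
            min_class, k,
        )

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics: list[dict] = []
    accuracies: list[float] = []
    for train_idx, test_idx in skf.split(X, y):
        est = DecisionTreeClassifier(
            criterion="gini", max_depth=max_depth, min_samples_leaf=min_leaf, random_state=0
        )
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        accuracies.append(100.0 * float(np.mean(pred == y[test_idx])))
        fold_metrics.append(_fold_metrics(y[test_idx], pred, labels))

    per_class = {}
    for label in labels:
        per_class[label] = {}
        for metric in ("sensitivity", "specificity", "precision"):
            values = [fm[label][metric] for fm in fold_metrics
                      if not math.isnan(fm[label][metric])]
            if values:
                per_class[label][metric] = float(np.mean(values))
            else:
                logger.warning("class %r: %s undefined in every fold", label, metric)
                per_class[label][metric] = math.nan
    return CvReport(folds=k, per_class=per_class,
                    overall_accuracy=float(np.mean(accuracies)))
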