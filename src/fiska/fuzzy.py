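"""Mamdani multi-input single-output fuzzy engine.

Trapezoidal membership, min firing, max aggregation of clipped consequents,
and center-of-gravity defuzzification on a sampled output universe. Categorical
inputs (urgency, ABO relation) run through the same machinery as crisp 0/1
encodings so inference is uniform across variables.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError, NoRuleFiredError, RuleBaseError

logger = logging.getLogger(__name__)

DEFAULT_RESOLUTION = 0.1


@dataclass(frozen=True)
class FuzzySet:
    """Trapezoid (a, b, c, d); b == c makes it triangular.

    Membership is 0 outside [a, d], ramps linearly on [a, b] and [c, d], and
    is 1 on the plateau [b, c]. With a degenerate edge (a == b or c == d) the
    plateau value applies at the shared point.
    """

    name: str
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if not (self.a <= self.b <= self.c <= self.d):
            raise ConfigError(
                f"fuzzy set {self.name!r}: breakpoints must satisfy a <= b <= c <= d, "
                f"got ({self.a}, {self.b}, {self.c}, {self.d})"
            )

    def membership(self, x):
        """Membership degree(s) in [0, 1]; accepts scalars or arrays."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        if self.b > self.a:
            rising = (x >= self.a) & (x < self.b)
            out = np.where(rising, (x - self.a) / (self.b - self.a), out)
        if self.d > self.c:
            falling = (x > self.c) & (x <= self.d)
            out = np.where(falling, (self.d - x) / (self.d - self.c), out)
        out = np.where((x >= self.b) & (x <= self.c), 1.0, out)
        return float(out) if out.ndim == 0 else out

    @property
    def plateau_center(self) -> float:
        return 0.5 * (self.b + self.c)


def trapezoid_membership(x: float, fset: FuzzySet) -> float:
    """Functional alias for :meth:`FuzzySet.membership`."""
    return fset.membership(x)


@dataclass(frozen=True)
class LinguisticVariable:
    """A named variable with a closed universe and an ordered list of sets."""

    name: str
    universe: tuple[float, float]
    sets: tuple[FuzzySet, ...]

    def __post_init__(self):
        lo, hi = self.universe
        if not lo < hi:
            raise ConfigError(f"variable {self.name!r}: universe must satisfy lo < hi")
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ConfigError(f"variable {self.name!r}: duplicate set names {names}")
        for s in self.sets:
            if s.a < lo or s.d > hi:
                raise ConfigError(
                    f"variable {self.name!r}: set {s.name!r} support [{s.a}, {s.d}] "
                    f"outside universe [{lo}, {hi}]"
                )
        object.__setattr__(self, "sets", tuple(self.sets))

    def set_named(self, name: str) -> FuzzySet:
        for s in self.sets:
            if s.name == name:
                return s
        raise RuleBaseError(f"variable {self.name!r} has no set {name!r}")

    def clamp(self, value: float) -> float:
        lo, hi = self.universe
        if value < lo or value > hi:
            logger.warning("clamping %s=%s to universe [%s, %s]", self.name, value, lo, hi)
            return min(max(value, lo), hi)
        return float(value)

    def fuzzify(self, value: float) -> dict[str, float]:
        """Membership degree of ``value`` in every set, clamping to the universe."""
        x = self.clamp(value)
        return {s.name: float(s.membership(x)) for s in self.sets}


def fuzzify(value: float, variable: LinguisticVariable) -> dict[str, float]:
    return variable.fuzzify(value)


@dataclass(frozen=True)
class FuzzyRule:
    """IF (var is set AND ...) THEN output is ``consequent``.

    Variables absent from the antecedent are unconstrained; an empty
    antecedent always fires at full strength.
    """

    antecedent: Mapping[str, str]
    consequent: str

    def __post_init__(self):
        object.__setattr__(self, "antecedent", dict(self.antecedent))


def firing_strength(rule: FuzzyRule, fuzzified: Mapping[str, Mapping[str, float]]) -> float:
    """Min over the rule's antecedent term degrees; 1.0 for an empty antecedent."""
    strength = 1.0
    for var, set_name in rule.antecedent.items():
        try:
            degrees = fuzzified[var]
        except KeyError:
            raise RuleBaseError(f"no fuzzified degrees for variable {var!r}")
        try:
            strength = min(strength, degrees[set_name])
        except KeyError:
            raise RuleBaseError(f"variable {var!r} has no set {set_name!r}")
    return strength


@dataclass
class RuleBase:
    """Input variables, the five-set output variable, and the rule list."""

    inputs: Sequence[LinguisticVariable]
    output: LinguisticVariable
    rules: Sequence[FuzzyRule]

    def __post_init__(self):
        self.inputs = list(self.inputs)
        self.rules = list(self.rules)
        if len(self.output.sets) != 5:
            raise ConfigError(
                f"output variable must have exactly 5 sets, got {len(self.output.sets)}"
            )
        if not self.rules:
            raise ConfigError("rule base must contain at least one rule")
        by_name = {v.name: v for v in self.inputs}
        for i, rule in enumerate(self.rules):
            for var, set_name in rule.antecedent.items():
                if var not in by_name:
                    raise RuleBaseError(f"rule {i}: unknown variable {var!r}")
                by_name[var].set_named(set_name)  # raises on unknown set
            self.output.set_named(rule.consequent)

    @property
    def input_names(self) -> list[str]:
        return [v.name for v in self.inputs]

    def variable(self, name: str) -> LinguisticVariable:
        for v in self.inputs:
            if v.name == name:
                return v
        raise RuleBaseError(f"unknown input variable {name!r}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def var_dict(v: LinguisticVariable) -> dict:
            return {
                "name": v.name,
                "universe": list(v.universe),
                "sets": [{"name": s.name, "a": s.a, "b": s.b, "c": s.c, "d": s.d}
                         for s in v.sets],
            }

        return {
            "inputs": [var_dict(v) for v in self.inputs],
            "output": var_dict(self.output),
            "rules": [{"antecedent": dict(r.antecedent), "consequent": r.consequent}
                      for r in self.rules],
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "RuleBase":
        def parse_var(d) -> LinguisticVariable:
            return LinguisticVariable(
                name=d["name"],
                universe=tuple(d["universe"]),
                sets=tuple(FuzzySet(s["name"], s["a"], s["b"], s["c"], s["d"])
                           for s in d["sets"]),
            )

        return cls(
            inputs=[parse_var(d) for d in doc["inputs"]],
            output=parse_var(doc["output"]),
            rules=[FuzzyRule(r["antecedent"], r["consequent"]) for r in doc["rules"]],
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RuleBase":
        """Load from a JSON string or file path."""
        text = str(source)
        if not text.lstrip().startswith("{"):
            with open(source) as fh:
                text = fh.read()
        return cls.from_dict(json.loads(text))


def output_grid(output: LinguisticVariable, resolution: float = DEFAULT_RESOLUTION) -> np.ndarray:
    if resolution <= 0:
        raise ConfigError("resolution must be > 0")
    lo, hi = output.universe
    n = int(round((hi - lo) / resolution))
    return lo + resolution * np.arange(n + 1)


def aggregate(
    rulebase: RuleBase,
    strengths: Sequence[float],
    resolution: float = DEFAULT_RESOLUTION,
) -> tuple[np.ndarray, np.ndarray]:
    """Max over rules of the strength-clipped consequent sets, sampled on the
    output universe. Returns ``(grid, membership)``.
    """
    if len(strengths) != len(rulebase.rules):
        raise RuleBaseError(
            f"{len(strengths)} strengths for {len(rulebase.rules)} rules"
        )
    grid = output_grid(rulebase.output, resolution)
    agg = np.zeros_like(grid)
    for rule, s in zip(rulebase.rules, strengths):
        if s <= 0:
            continue
        clipped = np.minimum(s, rulebase.output.set_named(rule.consequent).membership(grid))
        np.maximum(agg, clipped, out=agg)
    return grid, agg


def defuzzify_cog(aggregated: np.ndarray, grid: np.ndarray, inputs=None) -> float:
    """Discrete center of gravity sum(B*y)/sum(B) over the sample grid."""
    total = float(np.sum(aggregated))
    if total <= 0.0:
        raise NoRuleFiredError(inputs)
    return float(np.sum(aggregated * grid) / total)


def infer(
    inputs: Mapping[str, float],
    rulebase: RuleBase,
    resolution: float = DEFAULT_RESOLUTION,
    fallback: str | None = None,
) -> float:
    """Crisp output for one set of crisp inputs: fuzzify, fire, aggregate, COG.

    ``fallback`` names an output set (e.g. ``"medium"``) whose full-membership
    centroid is returned when no rule fires; a literal always-firing
    antecedent-free rule would instead flood every aggregate, so the fallback
    only engages on an empty one. Without a fallback an uncovered input raises
    :class:`NoRuleFiredError`.
    """
    fuzzified = {v.name: v.fuzzify(inputs[v.name]) for v in rulebase.inputs
                 if v.name in inputs}
    strengths = [firing_strength(rule, fuzzified) for rule in rulebase.rules]
    grid, agg = aggregate(rulebase, strengths, resolution)
    try:
        return defuzzify_cog(agg, grid, inputs)
    except NoRuleFiredError:
        if fallback is None:
            raise
        logger.info("no rule fired; falling back to output set %r", fallback)
        fset = rulebase.output.set_named(fallback)
        return defuzzify_cog(fset.membership(grid), grid, inputs)


def infer_batch(
    frame,
    rulebase: RuleBase,
    resolution: float = DEFAULT_RESOLUTION,
    fallback: str | None = None,
) -> np.ndarray:
    """Vectorized :func:`infer` over a DataFrame with one column per input
    variable. Returns an array of crisp scores aligned with the rows."""
    grid = output_grid(rulebase.output, resolution)
    cons = np.stack([rulebase.output.set_named(r.consequent).membership(grid)
                     for r in rulebase.rules])
    degrees: dict[str, dict[str, np.ndarray]] = {}
    for variable in rulebase.inputs:
        lo, hi = variable.universe
        values = np.asarray(frame[variable.name], dtype=float)
        clipped = np.clip(values, lo, hi)
        n_clamped = int(np.sum(values != clipped))
        if n_clamped:
            logger.info("clamping %d %s values to universe [%s, %s]",
                        n_clamped, variable.name, lo, hi)
        degrees[variable.name] = {s.name: s.membership(clipped)
                                  for s in variable.sets}
    n = len(frame)
    strengths = np.ones((n, len(rulebase.rules)))
    for j, rule in enumerate(rulebase.rules):
        for var, set_name in rule.antecedent.items():
            try:
                strengths[:, j] = np.minimum(strengths[:, j], degrees[var][set_name])
            except KeyError:
                raise RuleBaseError(f"variable {var!r} has no set {set_name!r}")
    fallback_curve = None
    if fallback is not None:
        fallback_curve = rulebase.output.set_named(fallback).membership(grid)
    out = np.empty(n)
    for i in range(n):
        agg = np.max(np.minimum(strengths[i][:, None], cons), axis=0)
        total = agg.sum()
        if total <= 0:
            if fallback_curve is None:
                raise NoRuleFiredError(dict(frame.iloc[i]))
            agg, total = fallback_curve, fallback_curve.sum()
        out[i] = float(agg @ grid / total)
    return out


def classify_output(score: float, output: LinguisticVariable) -> str:
    """Name of the output set with maximal membership at ``score`` (ties go to
    the lower-ordered set)."""
    degrees = [s.membership(score) for s in output.sets]
    return output.sets[int(np.argmax(degrees))].name


def rule_grid_size(variables: Sequence[LinguisticVariable]) -> int:
    """Size of the full Cartesian rule grid: product of per-variable set counts."""
    if not variables:
        raise ConfigError("need at least one variable")
    return int(math.prod(len(v.sets) for v in variables))


def load_default_variables() -> tuple[list[LinguisticVariable], LinguisticVariable]:
    """The packaged 8-input variable definition and output variable."""
    import importlib.resources

    ref = importlib.resources.files("fiska.data") / "default_variables.json"
    doc = json.loads(ref.read_text())
    inputs = [
        LinguisticVariable(
            d["name"], tuple(d["universe"]),
            tuple(FuzzySet(s["name"], s["a"], s["b"], s["c"], s["d"]) for s in d["sets"]),
        )
        for d in doc["inputs"]
    ]
    out = doc["output"]
    output = LinguisticVariable(
        out["name"], tuple(out["universe"]),
        tuple(FuzzySet(s["name"], s["a"], s["b"], s["c"], s["d"]) for s in out["sets"]),
    )
    return inputs, output
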