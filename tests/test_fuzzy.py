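import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiska import fuzzy
from fiska.errors import ConfigError, NoRuleFiredError, RuleBaseError
from fiska.fuzzy import (FuzzyRule, FuzzySet, LinguisticVariable, RuleBase,
                         aggregate, defuzzify_cog, firing_strength, infer,
                         output_grid, rule_grid_size, trapezoid_membership)


def cog_oracle(fset: FuzzySet, lo=0.0, hi=100.0, clip=1.0, n=2_000_001):
    """Dense-grid numeric centroid, independent of the engine's sampling."""
    ys = np.linspace(lo, hi, n)
    mu = np.minimum(fset.membership(ys), clip)
    return float(np.trapezoid(mu * ys, ys) / np.trapezoid(mu, ys))


@pytest.fixture
def simple_variable():
    return LinguisticVariable(
        "x", (0.0, 100.0),
        (FuzzySet("lo", 0, 0, 20, 40), FuzzySet("mid", 20, 40, 60, 80),
         FuzzySet("hi", 60, 80, 100, 100)),
    )


@pytest.fixture
def tiny_rulebase(simple_variable):
    output = LinguisticVariable(
        "priority", (0.0, 100.0),
        (FuzzySet("very_low", 0, 0, 0, 25), FuzzySet("low", 0, 25, 25, 50),
         FuzzySet("medium", 25, 50, 50, 75), FuzzySet("high", 50, 75, 75, 100),
         FuzzySet("very_high", 75, 100, 100, 100)),
    )
    rules = [
        FuzzyRule({"x": "lo"}, "very_low"),
        FuzzyRule({"x": "mid"}, "medium"),
        FuzzyRule({"x": "hi"}, "very_high"),
    ]
    return RuleBase([simple_variable], output, rules)


class TestTrapezoidMembership:
    trap = FuzzySet("t", 0, 20, 40, 60)

    @pytest.mark.parametrize("x, expected", [
        (10, 0.5), (30, 1.0), (70, 0.0), (-5, 0.0), (0, 0.0), (20, 1.0),
        (40, 1.0), (50, 0.5), (60, 0.0),
    ])
    def test_piecewise_values(self, x, expected):
        assert trapezoid_membership(x, self.trap) == pytest.approx(expected)

    def test_degenerate_edges_take_plateau_value(self):
        singleton = FuzzySet("s", 5, 5, 5, 5)
        assert singleton.membership(5) == 1.0
        assert singleton.membership(5.0001) == 0.0
        left_crisp = FuzzySet("l", 0, 0, 3, 6)
        assert left_crisp.membership(0) == 1.0

    def test_invalid_breakpoints_rejected(self):
        with pytest.raises(ConfigError):
            FuzzySet("bad", 10, 5, 20, 30)

    @given(st.floats(-50, 150))
    def test_range(self, x):
        assert 0.0 <= self.trap.membership(x) <= 1.0

    @given(st.floats(-10, 110), st.floats(0.0001, 0.01))
    @settings(max_examples=50)
    def test_continuity(self, x, eps):
        # trapezoids are Lipschitz with constant 1/min ramp width (here 1/20)
        assert abs(self.trap.membership(x) - self.trap.membership(x + eps)) <= eps / 20 + 1e-12


class TestFuzzify:
    def test_plateau_center_full_membership(self, simple_variable):
        degrees = simple_variable.fuzzify(50.0)
        assert degrees["mid"] == 1.0

    def test_symmetric_crossover_of_default_sets(self, default_variables):
        # urgency sets ramp 0.2 -> 0.8 in both directions; 0.5 is the crossover
        inputs, _ = default_variables
        urgency = next(v for v in inputs if v.name == "medical_urgency")
        degrees = urgency.fuzzify(0.5)
        assert degrees["non_urgent"] == pytest.approx(0.5)
        assert degrees["urgent"] == pytest.approx(0.5)

    def test_below_universe_clamps_to_edge(self, simple_variable):
        assert simple_variable.fuzzify(-10.0) == simple_variable.fuzzify(0.0)

    def test_above_universe_clamps_to_edge(self, simple_variable):
        assert simple_variable.fuzzify(250.0) == simple_variable.fuzzify(100.0)


class TestFiringStrength:
    def test_min_of_terms(self):
        rule = FuzzyRule({"a": "s1", "b": "s2", "c": "s3"}, "medium")
        fuzzified = {"a": {"s1": 0.3}, "b": {"s2": 0.7}, "c": {"s3": 1.0}}
        assert firing_strength(rule, fuzzified) == pytest.approx(0.3)

    def test_zero_term_kills_rule(self):
        rule = FuzzyRule({"a": "s1", "b": "s2"}, "medium")
        assert firing_strength(rule, {"a": {"s1": 0.0}, "b": {"s2": 0.9}}) == 0.0

    def test_empty_antecedent_fires_fully(self):
        assert firing_strength(FuzzyRule({}, "medium"), {}) == 1.0

    def test_unknown_set_raises(self):
        rule = FuzzyRule({"a": "nope"}, "medium")
        with pytest.raises(RuleBaseError):
            firing_strength(rule, {"a": {"s1": 0.5}})


class TestAggregate:
    def test_same_consequent_clips_at_max_strength(self, tiny_rulebase):
        rb = RuleBase(tiny_rulebase.inputs, tiny_rulebase.output,
                      [FuzzyRule({"x": "lo"}, "medium"), FuzzyRule({"x": "hi"}, "medium")])
        grid, agg = aggregate(rb, [0.3, 0.6], resolution=0.5)
        expected = np.minimum(0.6, rb.output.set_named("medium").membership(grid))
        np.testing.assert_allclose(agg, expected)

    def test_single_full_strength_rule_reproduces_set(self, tiny_rulebase):
        grid, agg = aggregate(tiny_rulebase, [0.0, 1.0, 0.0], resolution=0.5)
        np.testing.assert_allclose(
            agg, tiny_rulebase.output.set_named("medium").membership(grid))

    def test_all_zero_strengths(self, tiny_rulebase):
        _, agg = aggregate(tiny_rulebase, [0.0, 0.0, 0.0], resolution=0.5)
        assert np.all(agg == 0.0)

    def test_strength_count_mismatch(self, tiny_rulebase):
        with pytest.raises(RuleBaseError):
            aggregate(tiny_rulebase, [1.0], resolution=0.5)


class TestDefuzzifyCog:
    def test_rectangle(self):
        grid = np.arange(0, 100.01, 0.01)
        curve = ((grid >= 10) & (grid <= 30)).astype(float)
        assert defuzzify_cog(curve, grid) == pytest.approx(20.0, abs=1e-6)

    def test_symmetric_triangle(self):
        grid = np.arange(0, 100.001, 0.001)
        tri = FuzzySet("tri", 0, 50, 50, 100)
        assert defuzzify_cog(tri.membership(grid), grid) == pytest.approx(50.0, abs=1e-6)

    def test_two_equal_rectangles(self):
        # analytic centroid of [10,30] U [70,90] is 50; dense-grid oracle agrees
        grid = np.arange(0, 100.0005, 0.0005)
        curve = (((grid >= 10) & (grid <= 30)) | ((grid >= 70) & (grid <= 90))).astype(float)
        assert defuzzify_cog(curve, grid) == pytest.approx(50.0, abs=1e-6)
        oracle = float(np.trapezoid(curve * grid, grid) / np.trapezoid(curve, grid))
        assert oracle == pytest.approx(50.0, abs=1e-6)

    def test_zero_area_raises_with_inputs(self):
        grid = np.arange(0, 10.1, 0.1)
        with pytest.raises(NoRuleFiredError) as err:
            defuzzify_cog(np.zeros_like(grid), grid, inputs={"pra": 42})
        assert err.value.inputs == {"pra": 42}

    @pytest.mark.parametrize("height", [0.1, 0.25, 0.5, 0.9, 1.0])
    def test_clip_height_invariance_for_symmetric_set(self, height):
        grid = np.arange(0, 100.01, 0.01)
        mid = FuzzySet("m", 20, 40, 60, 80)  # symmetric about 50
        curve = np.minimum(height, mid.membership(grid))
        assert defuzzify_cog(curve, grid) == pytest.approx(50.0, abs=1e-9)


class TestInfer:
    def test_single_rule_gives_consequent_centroid(self, default_variables):
        inputs, output = default_variables
        rb = RuleBase(inputs, output,
                      [FuzzyRule({"medical_urgency": "urgent"}, "very_high")])
        features = {"medical_urgency": 1.0}
        got = infer(features, rb, resolution=0.01)
        vh = output.set_named("very_high")
        assert got == pytest.approx(cog_oracle(vh), abs=1e-2)

    def test_fig6_style_inputs_inside_output_universe(self, default_variables, fixtures_dir):
        rb = RuleBase.from_json(fixtures_dir / "rules.json")
        features = {
            "medical_urgency": 1, "pra": 75, "recipient_age": 28,
            "waiting_time": 200 / 365.25, "hla_mismatch": 3,
            "age_difference": 5, "predicted_survival": 6, "abo_identical": 1,
        }
        score = infer(features, rb, fallback="medium")
        assert 0.0 <= score <= 100.0

    def test_resolution_convergence(self, fixtures_dir):
        rb = RuleBase.from_json(fixtures_dir / "rules.json")
        features = {
            "medical_urgency": 0, "pra": 10, "recipient_age": 50,
            "waiting_time": 3.0, "hla_mismatch": 4, "age_difference": 8,
            "predicted_survival": 9, "abo_identical": 0,
        }
        coarse = infer(features, rb, resolution=0.1, fallback="medium")
        fine = infer(features, rb, resolution=0.05, fallback="medium")
        oracle = infer(features, rb, resolution=0.01, fallback="medium")
        assert abs(coarse - fine) < 0.1
        assert abs(fine - oracle) < 0.05

    def test_fallback_on_uncovered_input(self, default_variables):
        inputs, output = default_variables
        rb = RuleBase(inputs, output,
                      [FuzzyRule({"medical_urgency": "urgent"}, "very_high")])
        features = {"medical_urgency": 0.0}
        with pytest.raises(NoRuleFiredError):
            infer(features, rb)
        got = infer(features, rb, fallback="medium")
        assert got == pytest.approx(50.0, abs=0.1)

    def test_deterministic(self, fixtures_dir):
        rb = RuleBase.from_json(fixtures_dir / "rules.json")
        features = {"medical_urgency": 0, "pra": 40, "recipient_age": 33,
                    "waiting_time": 1.2, "hla_mismatch": 2, "age_difference": 3,
                    "predicted_survival": 12, "abo_identical": 1}
        runs = {infer(features, rb, fallback="medium") for _ in range(3)}
        assert len(runs) == 1

    def test_infer_batch_matches_scalar_infer(self, fixtures_dir):
        import pandas as pd

        rb = RuleBase.from_json(fixtures_dir / "rules.json")
        rng = np.random.default_rng(5)
        frame = pd.DataFrame({
            "medical_urgency": rng.integers(0, 2, 20),
            "pra": rng.uniform(0, 100, 20),
            "recipient_age": rng.uniform(1, 80, 20),
            "age_difference": rng.uniform(0, 50, 20),
            "hla_mismatch": rng.integers(0, 6, 20),
            "waiting_time": rng.uniform(0, 10, 20),
            "predicted_survival": rng.uniform(0, 20, 20),
            "abo_identical": rng.integers(0, 2, 20),
        })
        batch = fuzzy.infer_batch(frame, rb, fallback="medium")
        for i in range(len(frame)):
            single = infer(dict(frame.iloc[i]), rb, fallback="medium")
            assert batch[i] == pytest.approx(single, abs=1e-9)


class TestCogWithinSupport:
    def test_output_inside_aggregate_support(self, tiny_rulebase):
        grid, agg = aggregate(tiny_rulebase, [0.8, 0.0, 0.0], resolution=0.1)
        got = defuzzify_cog(agg, grid)
        support = grid[agg > 0]
        assert support.min() <= got <= support.max()


class TestRuleGridSize:
    def test_default_definition(self, default_variables):
        inputs, _ = default_variables
        assert rule_grid_size(inputs) == 13824
        assert sorted(len(v.sets) for v in inputs) == sorted([2, 4, 3, 3, 6, 4, 4, 2])

    def test_all_singletons(self):
        vars_ = [LinguisticVariable(f"v{i}", (0, 1), (FuzzySet("only", 0, 0, 1, 1),))
                 for i in range(4)]
        assert rule_grid_size(vars_) == 1

    def test_two_by_two(self):
        v = LinguisticVariable("v", (0, 1), (FuzzySet("a", 0, 0, 0, 1),
                                             FuzzySet("b", 0, 1, 1, 1)))
        w = LinguisticVariable("w", (0, 1), (FuzzySet("a", 0, 0, 0, 1),
                                             FuzzySet("b", 0, 1, 1, 1)))
        assert rule_grid_size([v, w]) == 4


class TestSerialization:
    def test_round_trip_is_loss_free(self, fixtures_dir, tmp_path):
        rb = RuleBase.from_json(fixtures_dir / "rules.json")
        path = tmp_path / "rules.json"
        rb.to_json(path)
        back = RuleBase.from_json(path)
        assert back.to_dict() == rb.to_dict()

    def test_round_trip_through_string(self, tiny_rulebase):
        text = tiny_rulebase.to_json()
        back = RuleBase.from_dict(json.loads(text))
        assert back.to_dict() == tiny_rulebase.to_dict()

    def test_output_must_have_five_sets(self, simple_variable):
        with pytest.raises(ConfigError):
            RuleBase([simple_variable], simple_variable,
                     [FuzzyRule({"x": "lo"}, "lo")])

    def test_rule_referencing_unknown_set_rejected(self, tiny_rulebase):
        with pytest.raises(RuleBaseError):
            RuleBase(tiny_rulebase.inputs, tiny_rulebase.output,
                     [FuzzyRule({"x": "nonexistent"}, "medium")])
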