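"""Engine-level tests: membership shapes, parsing, firing, defuzzification."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fuzzyact as fa
from fuzzyact.fuzzy import Atom, BoolOp, FuzzyRule, RuleBase

from _oracles import brute_force_activations, brute_force_defuzzify, brute_force_infer

MF = fa.MembershipFunction


class TestMembershipFunctions:
    @pytest.mark.parametrize(
        "mf, x, expected",
        [
            (MF.gaussian(0.0, 0.15), 0.0, 1.0),                # peak of gaussian
            (MF.sigmoid_increasing(2.0, 5.0), 2.0, 0.5),       # inflection
            (MF.sigmoid_decreasing(2.0, 5.0), 2.0, 0.5),
            (MF.triangle(-0.4, 0.0, 0.4), 0.2, 0.5),           # linear interpolation
            (MF.triangle(-0.4, 0.0, 0.4), 0.0, 1.0),
            (MF.triangle(-0.4, 0.0, 0.4), -0.5, 0.0),          # outside feet
            (MF.trapezoid(0.2, 0.6, np.inf, np.inf), 0.4, 0.5),
            (MF.trapezoid(0.2, 0.6, np.inf, np.inf), 5.0, 1.0),
            (MF.trapezoid(-np.inf, -np.inf, -0.6, -0.2), -1.0, 1.0),
            (MF.trapezoid(-np.inf, -np.inf, -0.6, -0.2), 0.0, 0.0),
            (MF.singleton(3.0), 3.0, 1.0),
            (MF.singleton(3.0), 3.4, 1.0),                     # inside the 0.5 window
            (MF.singleton(3.0), 3.6, 0.0),
        ],
    )
    def test_pointwise_values(self, mf, x, expected):
        assert mf(x) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "mf",
        [
            MF.gaussian(1.0, 0.3),
            MF.sigmoid_increasing(0.0, 3.0),
            MF.sigmoid_decreasing(0.0, 3.0),
            MF.triangle(-1.0, 0.0, 2.0),
            MF.trapezoid(-2.0, -1.0, 1.0, 2.0),
            MF.singleton(0.0),
        ],
    )
    def test_degrees_bounded(self, mf):
        x = np.linspace(-50, 50, 501)
        d = mf(x)
        assert np.all(d >= 0.0) and np.all(d <= 1.0)

    def test_vectorized_matches_scalar(self):
        mf = MF.trapezoid(-2.0, -1.0, 1.0, 2.0)
        xs = np.linspace(-3, 3, 41)
        assert np.allclose(mf(xs), [mf(float(x)) for x in xs])

    @pytest.mark.parametrize(
        "build",
        [
            lambda: MF.gaussian(0.0, 0.0),
            lambda: MF.gaussian(np.nan, 1.0),
            lambda: MF.sigmoid_increasing(0.0, -1.0),
            lambda: MF.triangle(1.0, 0.0, 2.0),
            lambda: MF.trapezoid(0.0, 2.0, 1.0, 3.0),
            lambda: MF.trapezoid(-np.inf, -np.inf, np.inf, np.inf),
            lambda: MF.singleton(0.0, 0.0),
        ],
    )
    def test_invalid_parameters(self, build):
        with pytest.raises(fa.ParameterError):
            build()

    def test_non_finite_input_rejected(self):
        with pytest.raises(fa.InputError):
            MF.gaussian(0.0, 1.0)(np.nan)


class TestSlopeFromStd:
    def test_reference_value(self):
        # sqrt(8 ln 2) evaluated independently
        assert fa.slope_from_std(1.0) == pytest.approx(2.3548200450309493, rel=1e-12)

    def test_reciprocal_point(self):
        assert fa.slope_from_std(2.3548200450309493) == pytest.approx(1.0, rel=1e-12)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_doubling_std_halves_slope(self, std):
        assert fa.slope_from_std(2 * std) == pytest.approx(fa.slope_from_std(std) / 2, rel=1e-9)

    @pytest.mark.parametrize("bad", [0.0, -1.0, np.nan, np.inf])
    def test_invalid_std(self, bad):
        with pytest.raises(fa.ParameterError):
            fa.slope_from_std(bad)


SINGLE_RULE_SRC = """
FUNCTION_BLOCK toy
VAR_INPUT
    A : REAL;
END_VAR
VAR_OUTPUT
    Out : REAL;
END_VAR
FUZZIFY A
    RANGE := (0 .. 10);
    TERM x := gauss 5 1;
END_FUZZIFY
DEFUZZIFY Out
    RANGE := (-1 .. 1);
    TERM y := gauss 0.5 0.2;
END_DEFUZZIFY
RULEBLOCK rules
    RULE 1: IF (A IS x) THEN Out IS y;
END_RULEBLOCK
END_FUNCTION_BLOCK
"""


class TestParser:
    def test_default_rulebase_structure(self, rb):
        assert len(rb.rules) == 30
        assert [r.number for r in rb.rules] == list(range(1, 31))
        out = rb.variables[rb.output]
        assert set(out.categories) == {
            "high_GoF", "GoF", "low_GoF", "no_effect", "low_LoF", "LoF", "high_LoF",
        }
        assert set(rb.input_names) == {"Mutation", "Recurrence", "Expression", "CN"}
        assert len(rb.variables["Mutation"].categories) == 9  # 8 classes + No_Mutation

    def test_single_rule_file(self):
        rb = fa.parse_rulebase(SINGLE_RULE_SRC)
        assert len(rb.rules) == 1
        assert rb.rules[0].antecedent == Atom("A", "x")
        assert rb.rules[0].consequent == "y"

    def test_roundtrip_identity(self, rb):
        rb2 = fa.parse_rulebase(fa.rulebase_to_fcl(rb))
        assert rb2.rules == rb.rules
        assert rb2.variables == rb.variables
        assert rb2.output == rb.output

    def test_unknown_category_is_parse_error_with_line(self):
        src = SINGLE_RULE_SRC.replace("THEN Out IS y", "THEN Out IS nope")
        with pytest.raises(fa.ParseError, match="nope"):
            fa.parse_rulebase(src)

    def test_unknown_variable_in_rule(self):
        src = SINGLE_RULE_SRC.replace("IF (A IS x)", "IF (B IS x)")
        with pytest.raises(fa.ParseError, match="B"):
            fa.parse_rulebase(src)

    def test_duplicate_rule_number(self):
        src = SINGLE_RULE_SRC.replace(
            "RULE 1: IF (A IS x) THEN Out IS y;",
            "RULE 1: IF (A IS x) THEN Out IS y;\n    RULE 1: IF (A IS x) THEN Out IS y;",
        )
        with pytest.raises(fa.ParseError, match="duplicate"):
            fa.parse_rulebase(src)

    def test_malformed_syntax_names_line(self):
        src = SINGLE_RULE_SRC.replace("TERM x := gauss 5 1;", "TERM x == gauss 5 1;")
        with pytest.raises(fa.ParseError, match=r"line \d+"):
            fa.parse_rulebase(src)


def _random_system(rng):
    """Random small rule system (<=3 input variables, <=6 rules)."""
    n_vars = rng.integers(1, 4)
    variables = {}
    for i in range(n_vars):
        cats = {}
        for j in range(rng.integers(2, 4)):
            kind = rng.integers(0, 3)
            center = float(rng.uniform(-1, 1))
            if kind == 0:
                cats[f"c{j}"] = MF.gaussian(center, float(rng.uniform(0.1, 0.8)))
            elif kind == 1:
                cats[f"c{j}"] = MF.sigmoid_increasing(center, float(rng.uniform(0.5, 6)))
            else:
                half = float(rng.uniform(0.2, 1.0))
                cats[f"c{j}"] = MF.triangle(center - half, center, center + half)
        variables[f"V{i}"] = fa.LinguisticVariable(f"V{i}", (-2.0, 2.0), cats)
    out_cats = {
        "neg": MF.gaussian(-0.5, 0.2),
        "zero": MF.gaussian(0.0, 0.2),
        "pos": MF.gaussian(0.5, 0.2),
    }
    variables["Out"] = fa.LinguisticVariable("Out", (-1.0, 1.0), out_cats)

    def random_tree(depth):
        if depth == 0 or rng.random() < 0.4:
            v = f"V{rng.integers(0, n_vars)}"
            cat = rng.choice(list(variables[v].categories))
            return Atom(v, str(cat))
        op = "and" if rng.random() < 0.5 else "or"
        return BoolOp(op, tuple(random_tree(depth - 1) for _ in range(rng.integers(2, 4))))

    rules = [
        FuzzyRule(k + 1, random_tree(2), str(rng.choice(list(out_cats))))
        for k in range(rng.integers(1, 7))
    ]
    return RuleBase(variables, "Out", rules)


class TestInference:
    def test_fire_rules_crisp_extremes(self, rb, sep_expr_fit, sep_expr_var):
        rb2 = rb.replace_variable(sep_expr_var)
        inputs = {"Mutation": 0.0, "Recurrence": 1.0,
                  "Expression": sep_expr_fit.m_high + 3.0, "CN": 1.0}
        acts = fa.fire_rules(rb2, inputs)
        assert acts[0] == pytest.approx(1.0)  # rule 1 fully on
        # every truncating / no-mutation rule is off (mutation singleton mismatch)
        assert np.all(acts[18:] == 0.0)

    def test_fire_rules_at_inflection(self, rb, sep_expr_fit, sep_expr_var):
        rb2 = rb.replace_variable(sep_expr_var)
        inputs = {"Mutation": 0.0, "Recurrence": 1.0,
                  "Expression": sep_expr_fit.m_high, "CN": 0.0}
        acts = fa.fire_rules(rb2, inputs)
        assert acts[1] == pytest.approx(0.5, abs=1e-9)  # rule 2: high expr, neutral CN

    def test_missing_input_raises(self, rb):
        with pytest.raises(fa.InputError, match="Recurrence"):
            fa.fire_rules(rb, {"Mutation": 0.0, "Expression": 0.0, "CN": 0.0})

    def test_activations_match_tree_walk_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            system = _random_system(rng)
            inputs = {f"V{i}": float(rng.uniform(-2, 2)) for i in range(3)}
            got = fa.fire_rules(system, inputs)
            expected = brute_force_activations(system, inputs)
            assert np.allclose(got, expected, atol=1e-12)

    def test_defuzzify_matches_trapezoid_oracle(self, rb):
        rng = np.random.default_rng(11)
        for _ in range(10):
            acts = rng.uniform(0, 1, len(rb.rules))
            got = fa.aggregate_and_defuzzify(rb, acts, resolution=2001)
            expected = brute_force_defuzzify(rb, acts.tolist(), resolution=2001)
            assert got == pytest.approx(expected, abs=1e-6)

    def test_resolution_convergence(self, rb):
        rng = np.random.default_rng(13)
        acts = rng.uniform(0, 1, len(rb.rules))
        coarse = fa.aggregate_and_defuzzify(rb, acts, resolution=2001)
        fine = fa.aggregate_and_defuzzify(rb, acts, resolution=20001)
        assert coarse == pytest.approx(fine, abs=1e-3)

    def test_resolution_floor_enforced(self, rb):
        with pytest.raises(fa.ParameterError):
            fa.aggregate_and_defuzzify(rb, np.zeros(len(rb.rules)), resolution=50)

    def test_end_to_end_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            system = _random_system(rng)
            inputs = {f"V{i}": float(rng.uniform(-2, 2)) for i in range(3)}
            got = fa.infer(system, inputs)
            expected = brute_force_infer(system, inputs)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_empty_curve_defuzzifies_to_zero(self, rb):
        assert fa.aggregate_and_defuzzify(rb, np.zeros(len(rb.rules))) == 0.0

    def test_no_effect_only_centers_at_zero(self, rb):
        acts = np.zeros(len(rb.rules))
        acts[29] = 1.0  # rule 30 -> no_effect, symmetric about 0
        assert fa.aggregate_and_defuzzify(rb, acts) == pytest.approx(0.0, abs=1e-12)

    def test_mirror_consequents_fired_equally_cancel(self, rb):
        acts = np.zeros(len(rb.rules))
        acts[4] = 0.7   # rule 5 -> GoF (gauss at +2/3)
        acts[22] = 0.7  # rule 23 -> LoF (gauss at -2/3)
        assert fa.aggregate_and_defuzzify(rb, acts) == pytest.approx(0.0, abs=1e-12)


class TestAggregationProperties:
    def test_union_monotone_in_added_rules(self, rb):
        rng = np.random.default_rng(5)
        acts = rng.uniform(0, 1, len(rb.rules))
        reduced = acts.copy()
        reduced[7] = 0.0
        _, full = fa.aggregated_output(rb, acts)
        _, less = fa.aggregated_output(rb, reduced)
        assert np.all(full >= less - 1e-15)

    def test_duplicate_rule_is_absorbed(self, rb):
        dup = RuleBase(
            dict(rb.variables), rb.output,
            list(rb.rules) + [FuzzyRule(99, rb.rules[0].antecedent, rb.rules[0].consequent)],
        )
        rng = np.random.default_rng(17)
        acts = rng.uniform(0, 1, len(rb.rules))
        acts_dup = np.concatenate([acts, [acts[0]]])
        assert fa.aggregate_and_defuzzify(dup, acts_dup) == pytest.approx(
            fa.aggregate_and_defuzzify(rb, acts), abs=1e-12
        )

    def test_scores_bounded_on_random_activations(self, rb):
        rng = np.random.default_rng(23)
        acts = rng.uniform(0, 1, (len(rb.rules), 500))
        scores = fa.aggregate_and_defuzzify(rb, acts)
        assert np.all(np.abs(scores) <= 1.0)
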