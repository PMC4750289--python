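"""Mamdani-style fuzzy inference engine.

Implements the primitives the activity-scoring pipeline is built on:
parametric membership functions, linguistic variables, IF/THEN rules over
fuzzy categories, min/max rule firing, union (max) aggregation of clipped
consequents and centroid defuzzification on a uniform grid.

Operator choices follow the IEC 61131-7 FCL defaults: AND = minimum,
OR = maximum, rule activation clips the consequent at the antecedent
degree, and accumulation is pointwise maximum.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Union

import numpy as np
from scipy.special import expit

from .errors import InputError, ParameterError, ParseError

__all__ = [
    "MembershipFunction",
    "LinguisticVariable",
    "Atom",
    "BoolOp",
    "FuzzyRule",
    "RuleBase",
    "slope_from_std",
    "evaluate_membership",
    "fire_rules",
    "aggregated_output",
    "aggregate_and_defuzzify",
    "infer",
    "parse_rulebase",
    "rulebase_to_fcl",
]

#: Full-width-at-half-maximum constant: a Gaussian falls to 1/2 at
#: mean ± std * sqrt(2 ln 2); the matching sigmoid slope is sqrt(8 ln 2)/std.
SQRT_8_LN2 = math.sqrt(8.0 * math.log(2.0))

#: Degree below which a rule is treated as not fired during aggregation.
ZERO_ACTIVATION = 0.0

#: Default number of grid points for centroid defuzzification.
DEFAULT_RESOLUTION = 2001

#: Half-width of the matching window of singleton memberships on integer codes.
SINGLETON_TOLERANCE = 0.5


def slope_from_std(std: float) -> float:
    """Sigmoid slope matching the half-maximum width of a Gaussian.

    A sigmoid 1/(1+exp(-a(x-c))) crosses 0.5 at its inflection c; choosing
    a = sqrt(8 ln 2)/std makes its rise mimic a Gaussian of standard
    deviation ``std`` (whose full width at half maximum is std*sqrt(8 ln 2)).
    """
    if not (isinstance(std, (int, float)) and math.isfinite(std) and std > 0):
        raise ParameterError(f"std must be a finite positive number, got {std!r}")
    return SQRT_8_LN2 / float(std)


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ParameterError(f"{name}: parameter {v!r} is not finite")


@dataclass(frozen=True)
class MembershipFunction:
    """Parametric shape mapping a crisp value to a degree in [0, 1].

    Supported kinds and their ``params``:

    - ``sigmoid_increasing`` / ``sigmoid_decreasing``: (inflection c, slope a>0)
    - ``gaussian``: (mean, std>0)
    - ``triangle``: (left, peak, right) with left <= peak <= right
    - ``trapezoid``: (left_foot, left_shoulder, right_shoulder, right_foot);
      feet may be +-inf to model saturated shoulders
    - ``singleton``: (location, tolerance) matching |x - location| < tolerance
    """

    kind: str
    params: tuple

    # -- constructors ------------------------------------------------------

    @classmethod
    def sigmoid_increasing(cls, c: float, a: float) -> "MembershipFunction":
        _require_finite("sigmoid", c, a)
        if a <= 0:
            raise ParameterError(f"sigmoid slope must be > 0, got {a}")
        return cls("sigmoid_increasing", (float(c), float(a)))

    @classmethod
    def sigmoid_decreasing(cls, c: float, a: float) -> "MembershipFunction":
        _require_finite("sigmoid", c, a)
        if a <= 0:
            raise ParameterError(f"sigmoid slope must be > 0, got {a}")
        return cls("sigmoid_decreasing", (float(c), float(a)))

    @classmethod
    def gaussian(cls, mean: float, std: float) -> "MembershipFunction":
        _require_finite("gaussian", mean, std)
        if std <= 0:
            raise ParameterError(f"gaussian std must be > 0, got {std}")
        return cls("gaussian", (float(mean), float(std)))

    @classmethod
    def triangle(cls, left: float, peak: float, right: float) -> "MembershipFunction":
        _require_finite("triangle", left, peak, right)
        if not (left <= peak <= right) or left == right:
            raise ParameterError(f"triangle needs left <= peak <= right, got {(left, peak, right)}")
        return cls("triangle", (float(left), float(peak), float(right)))

    @classmethod
    def trapezoid(cls, a: float, b: float, c: float, d: float) -> "MembershipFunction":
        if any(math.isnan(v) for v in (a, b, c, d)):
            raise ParameterError("trapezoid: NaN parameter")
        if not (a <= b <= c <= d):
            raise ParameterError(f"trapezoid needs a <= b <= c <= d, got {(a, b, c, d)}")
        if not (math.isfinite(b) or math.isfinite(c)):
            raise ParameterError("trapezoid needs a finite plateau")
        return cls("trapezoid", (float(a), float(b), float(c), float(d)))

    @classmethod
    def singleton(cls, location: float, tolerance: float = SINGLETON_TOLERANCE) -> "MembershipFunction":
        _require_finite("singleton", location, tolerance)
        if tolerance <= 0:
            raise ParameterError(f"singleton tolerance must be > 0, got {tolerance}")
        return cls("singleton", (float(location), float(tolerance)))

    # -- evaluation --------------------------------------------------------

    def __call__(self, x):
        """Evaluate the membership degree at ``x`` (scalar or array)."""
        arr = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise InputError(f"membership input contains non-finite values: {x!r}")
        out = self._evaluate(arr)
        if arr.ndim == 0:
            return float(out)
        return out

    def _evaluate(self, x: np.ndarray) -> np.ndarray:
        kind, p = self.kind, self.params
        if kind == "sigmoid_increasing":
            c, a = p
            return expit(a * (x - c))
        if kind == "sigmoid_decreasing":
            c, a = p
            return expit(-a * (x - c))
        if kind == "gaussian":
            mean, std = p
            return np.exp(-((x - mean) ** 2) / (2.0 * std * std))
        if kind == "triangle":
            left, peak, right = p
            return self._trapezoid_eval(x, left, peak, peak, right)
        if kind == "trapezoid":
            a_, b_, c_, d_ = p
            return self._trapezoid_eval(x, a_, b_, c_, d_)
        if kind == "singleton":
            loc, tol = p
            return (np.abs(x - loc) < tol).astype(float)
        raise ParameterError(f"unknown membership kind {kind!r}")

    @staticmethod
    def _trapezoid_eval(x: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
        shape = np.shape(x)
        xa = np.atleast_1d(np.asarray(x, dtype=float))
        deg = np.zeros_like(xa)
        deg[(xa >= b) & (xa <= c)] = 1.0
        if math.isfinite(a) and b > a:
            rising = (xa > a) & (xa < b)
            deg[rising] = (xa[rising] - a) / (b - a)
        if math.isfinite(d) and d > c:
            falling = (xa > c) & (xa < d)
            deg[falling] = (d - xa[falling]) / (d - c)
        return deg.reshape(shape)


def evaluate_membership(mf: MembershipFunction, x) -> float:
    """Degree of ``x`` in the category described by ``mf`` (in [0, 1])."""
    return mf(x)


@dataclass(frozen=True)
class LinguisticVariable:
    """A named quantity with overlapping fuzzy categories on a real domain."""

    name: str
    domain: tuple
    categories: Mapping[str, MembershipFunction]

    def __post_init__(self):
        lo, hi = self.domain
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ParameterError(f"variable {self.name!r}: domain must be a finite interval lo < hi, got {self.domain}")
        if not self.categories:
            raise ParameterError(f"variable {self.name!r}: needs at least one category")
        object.__setattr__(self, "categories", dict(self.categories))
        grid = np.linspace(lo, hi, 101)
        for label, mf in self.categories.items():
            if float(np.max(mf(grid))) <= 0.0:
                raise ParameterError(
                    f"variable {self.name!r}: category {label!r} has no support on the domain {self.domain}"
                )

    def evaluate(self, label: str, x):
        try:
            mf = self.categories[label]
        except KeyError:
            raise InputError(f"variable {self.name!r} has no category {label!r}") from None
        return mf(x)


# -- rules ---------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    """Leaf predicate ``variable IS category``."""

    var: str
    category: str


@dataclass(frozen=True)
class BoolOp:
    """AND/OR combination of sub-expressions (min/max under Mamdani)."""

    op: str  # "and" | "or"
    operands: tuple

    def __post_init__(self):
        if self.op not in ("and", "or"):
            raise ParameterError(f"unknown boolean operator {self.op!r}")
        if len(self.operands) < 2:
            raise ParameterError("boolean node needs >= 2 operands")


Node = Union[Atom, BoolOp]


def _iter_atoms(node: Node) -> Iterable[Atom]:
    if isinstance(node, Atom):
        yield node
    else:
        for child in node.operands:
            yield from _iter_atoms(child)


@dataclass(frozen=True)
class FuzzyRule:
    """IF <antecedent> THEN <output variable> IS <consequent category>."""

    number: int
    antecedent: Node
    consequent: str

    def atoms(self) -> list[Atom]:
        return list(_iter_atoms(self.antecedent))


@dataclass
class RuleBase:
    """Linguistic variables plus an ordered rule collection.

    Exactly one variable (``output``) is the consequent variable; all other
    variables may appear in antecedents. Consequent membership curves sampled
    on the output grid are cached per resolution, and survive
    :meth:`replace_variable` calls that do not touch the output variable.
    """

    variables: dict
    output: str
    rules: list
    _curve_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.output not in self.variables:
            raise ParameterError(f"output variable {self.output!r} is not declared")
        out_var = self.variables[self.output]
        numbers = [r.number for r in self.rules]
        if len(set(numbers)) != len(numbers):
            dupes = sorted({n for n in numbers if numbers.count(n) > 1})
            raise ParseError(f"duplicate rule numbers: {dupes}")
        for rule in self.rules:
            if rule.consequent not in out_var.categories:
                raise ParseError(
                    f"rule {rule.number}: consequent {rule.consequent!r} is not a category of {self.output!r}"
                )
            for atom in rule.atoms():
                if atom.var not in self.variables:
                    raise ParseError(f"rule {rule.number}: unknown variable {atom.var!r}")
                if atom.var == self.output:
                    raise ParseError(f"rule {rule.number}: output variable used in antecedent")
                if atom.category not in self.variables[atom.var].categories:
                    raise ParseError(
                        f"rule {rule.number}: variable {atom.var!r} has no category {atom.category!r}"
                    )

    @property
    def input_names(self) -> list[str]:
        return [n for n in self.variables if n != self.output]

    def referenced_inputs(self) -> set[str]:
        return {atom.var for rule in self.rules for atom in rule.atoms()}

    def replace_variable(self, variable: LinguisticVariable) -> "RuleBase":
        """Return a copy with ``variable`` swapped in by name.

        Used to substitute the per-gene fitted expression variable; the
        cached output curves are shared when the output variable is untouched.
        """
        if variable.name not in self.variables:
            raise InputError(f"no variable named {variable.name!r} to replace")
        new_vars = dict(self.variables)
        new_vars[variable.name] = variable
        cache = self._curve_cache if variable.name != self.output else {}
        return RuleBase(new_vars, self.output, list(self.rules), cache)

    def output_curves(self, resolution: int = DEFAULT_RESOLUTION):
        """Grid over the output domain and per-rule consequent curves."""
        if resolution < 101:
            raise ParameterError(f"resolution must be >= 101, got {resolution}")
        cached = self._curve_cache.get(resolution)
        if cached is None:
            lo, hi = self.variables[self.output].domain
            grid = np.linspace(lo, hi, int(resolution))
            out_var = self.variables[self.output]
            curves = np.vstack([out_var.categories[r.consequent](grid) for r in self.rules]) if self.rules else np.zeros((0, resolution))
            cached = (grid, curves)
            self._curve_cache[resolution] = cached
        return cached


# -- inference -----------------------------------------------------------


def _eval_node(node: Node, variables: Mapping[str, LinguisticVariable], inputs: Mapping):
    if isinstance(node, Atom):
        if node.var not in inputs:
            raise InputError(f"missing crisp input for variable {node.var!r}")
        return variables[node.var].evaluate(node.category, inputs[node.var])
    combine = np.minimum if node.op == "and" else np.maximum
    acc = _eval_node(node.operands[0], variables, inputs)
    for child in node.operands[1:]:
        acc = combine(acc, _eval_node(child, variables, inputs))
    return acc


def fire_rules(rb: RuleBase, crisp_inputs: Mapping) -> np.ndarray:
    """Antecedent activation of every rule at the given crisp inputs.

    ``crisp_inputs`` maps variable names to scalars or equally-shaped arrays;
    the result has shape ``(n_rules,) + input_shape``. AND combines leaf
    degrees by minimum, OR by maximum.
    """
    missing = rb.referenced_inputs() - set(crisp_inputs)
    if missing:
        raise InputError(f"missing crisp inputs for variables: {sorted(missing)}")
    acts = [np.asarray(_eval_node(r.antecedent, rb.variables, crisp_inputs), dtype=float) for r in rb.rules]
    return np.stack(acts) if acts else np.zeros((0,))


def aggregated_output(rb: RuleBase, activations, resolution: int = DEFAULT_RESOLUTION):
    """Union-aggregated output membership curve.

    Each rule's consequent curve is clipped (minimum) at the rule's
    activation and the clipped curves are merged pointwise by maximum.
    Returns ``(grid, membership)`` where membership has shape
    ``(resolution,) + activation_tail_shape``.
    """
    grid, curves = rb.output_curves(resolution)
    act = np.asarray(activations, dtype=float)
    if act.shape[0] != len(rb.rules):
        raise InputError(f"expected {len(rb.rules)} activations, got {act.shape[0]}")
    scalar = act.ndim == 1
    act2 = act[:, None] if scalar else act.reshape(act.shape[0], -1)
    agg = np.zeros((grid.size, act2.shape[1]))
    for r in range(act2.shape[0]):
        col = act2[r]
        if not np.any(col > ZERO_ACTIVATION):
            continue
        np.maximum(agg, np.minimum(curves[r][:, None], col[None, :]), out=agg)
    if scalar:
        return grid, agg[:, 0]
    return grid, agg.reshape((grid.size,) + act.shape[1:])


def aggregate_and_defuzzify(rb: RuleBase, activations, resolution: int = DEFAULT_RESOLUTION):
    """Centroid of the union-aggregated output curve.

    Returns sum(x*m(x))/sum(m(x)) over a uniform grid spanning the output
    domain, with trapezoidal end-weights (the two boundary points count
    half), i.e. the ratio of the trapezoidal-rule integrals of x*m and m.
    An identically-zero curve defuzzifies to 0 (the neutral score).
    Accepts an activation vector (returns a float) or a matrix with trailing
    batch axes (returns an array of matching batch shape).
    """
    act = np.asarray(activations, dtype=float)
    grid, agg = aggregated_output(rb, act, resolution)
    flat = agg.reshape(grid.size, -1)
    weights = np.ones_like(grid)
    weights[0] = weights[-1] = 0.5
    mass = weights @ flat
    moment = (grid * weights) @ flat
    safe = np.where(mass > 0.0, mass, 1.0)
    score = np.where(mass > 0.0, moment / safe, 0.0)
    if act.ndim == 1:
        return float(score[0])
    return score.reshape(act.shape[1:])


def infer(rb: RuleBase, crisp_inputs: Mapping, resolution: int = DEFAULT_RESOLUTION):
    """Full Mamdani inference: fire all rules, aggregate and defuzzify."""
    return aggregate_and_defuzzify(rb, fire_rules(rb, crisp_inputs), resolution)


# -- FCL-style parsing ---------------------------------------------------
#
# Supported subset of IEC 61131-7 Fuzzy Control Language:
#   FUNCTION_BLOCK <name> ... END_FUNCTION_BLOCK
#   VAR_INPUT / VAR_OUTPUT blocks declaring REAL variables
#   FUZZIFY <var> / DEFUZZIFY <var> blocks with
#     RANGE := (lo .. hi);
#     TERM <label> := <shape> <numbers...>;
#       shapes: sigm <gain> <center> (negative gain = decreasing),
#               gauss <mean> <std>, trian a b c, trape a b c d,
#               singleton <loc> [tol]
#     METHOD / DEFAULT lines are accepted and ignored.
#   RULEBLOCK with optional AND/OR/ACT/ACCU operator lines (ignored; the
#   engine is fixed to MIN/MAX) and numbered rules
#     RULE n: IF <expr> THEN <outvar> IS <category>;
#   where <expr> combines parenthesised "var IS category" atoms with
#   AND/OR (AND binds tighter). Comments: // line and (* block *).


_KEYWORDS_SKIP_LINE = {"METHOD", "DEFAULT", "AND", "OR", "ACT", "ACCU"}

_TOKEN_SPEC = [
    ("COMMENT", r"//[^\n]*|\(\*.*?\*\)"),
    ("ASSIGN", r":="),
    ("RANGE_DOTS", r"\.\."),
    ("NUMBER", r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?|[-+]?inf\b"),
    ("IDENT", r"[A-Za-z_][A-Za-z0-9_]*"),
    ("SYMBOL", r"[():;,]"),
]
_TOKEN_RE = re.compile("|".join(f"(?P<{k}>{v})" for k, v in _TOKEN_SPEC), re.S)


@dataclass(frozen=True)
class _Token:
    kind: str
    value: str
    line: int


def _tokenize(text: str) -> list[_Token]:
    tokens = []
    pos, line = 0, 1
    n = len(text)
    while pos < n:
        ch = text[pos]
        if ch in " \t\r":
            pos += 1
            continue
        if ch == "\n":
            line += 1
            pos += 1
            continue
        m = _TOKEN_RE.match(text, pos)
        if not m or m.start() != pos:
            raise ParseError(f"unexpected character {ch!r}", line)
        kind = m.lastgroup
        value = m.group()
        if kind != "COMMENT":
            tokens.append(_Token(kind, value, line))
        line += value.count("\n")
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[_Token]):
        self.tokens = tokens
        self.i = 0

    def peek(self) -> _Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            last = self.tokens[-1].line if self.tokens else 1
            raise ParseError("unexpected end of file", last)
        self.i += 1
        return tok

    def expect_symbol(self, sym: str) -> _Token:
        tok = self.next()
        if tok.value != sym:
            raise ParseError(f"expected {sym!r}, found {tok.value!r}", tok.line)
        return tok

    def expect_keyword(self, word: str) -> _Token:
        tok = self.next()
        if tok.kind != "IDENT" or tok.value.upper() != word:
            raise ParseError(f"expected {word}, found {tok.value!r}", tok.line)
        return tok

    def expect_ident(self) -> _Token:
        tok = self.next()
        if tok.kind != "IDENT":
            raise ParseError(f"expected identifier, found {tok.value!r}", tok.line)
        return tok

    def expect_number(self) -> float:
        tok = self.next()
        if tok.kind != "NUMBER":
            raise ParseError(f"expected number, found {tok.value!r}", tok.line)
        v = tok.value.replace("inf", "inf")
        return float(v)

    def at_keyword(self, *words: str) -> bool:
        tok = self.peek()
        return tok is not None and tok.kind == "IDENT" and tok.value.upper() in words

    def skip_to_semicolon(self) -> None:
        while True:
            tok = self.next()
            if tok.value == ";":
                return


def _parse_term(p: _Parser) -> tuple[str, MembershipFunction]:
    p.expect_keyword("TERM")
    label = p.expect_ident().value
    p.expect_symbol(":=")
    shape_tok = p.expect_ident()
    shape = shape_tok.value.lower()
    nums = []
    while p.peek() is not None and p.peek().kind == "NUMBER":
        nums.append(p.expect_number())
    p.expect_symbol(";")
    try:
        if shape in ("sigm", "sigmoid"):
            if len(nums) != 2:
                raise ParameterError("sigm needs <gain> <center>")
            gain, center = nums
            if gain == 0:
                raise ParameterError("sigm gain must be nonzero")
            if gain > 0:
                return label, MembershipFunction.sigmoid_increasing(center, gain)
            return label, MembershipFunction.sigmoid_decreasing(center, -gain)
        if shape == "gauss":
            if len(nums) != 2:
                raise ParameterError("gauss needs <mean> <std>")
            return label, MembershipFunction.gaussian(*nums)
        if shape == "trian":
            if len(nums) != 3:
                raise ParameterError("trian needs 3 parameters")
            return label, MembershipFunction.triangle(*nums)
        if shape == "trape":
            if len(nums) != 4:
                raise ParameterError("trape needs 4 parameters")
            return label, MembershipFunction.trapezoid(*nums)
        if shape == "singleton":
            if len(nums) == 1:
                return label, MembershipFunction.singleton(nums[0])
            if len(nums) == 2:
                return label, MembershipFunction.singleton(nums[0], nums[1])
            raise ParameterError("singleton needs <location> [tolerance]")
    except ParameterError as exc:
        raise ParseError(f"TERM {label}: {exc}", shape_tok.line) from exc
    raise ParseError(f"unknown membership shape {shape!r}", shape_tok.line)


def _parse_fuzzify_block(p: _Parser, end_word: str) -> tuple[str, LinguisticVariable]:
    name_tok = p.expect_ident()
    name = name_tok.value
    domain = None
    terms: dict[str, MembershipFunction] = {}
    while True:
        if p.at_keyword(end_word):
            p.next()
            break
        if p.at_keyword("RANGE"):
            p.next()
            p.expect_symbol(":=")
            p.expect_symbol("(")
            lo = p.expect_number()
            tok = p.next()
            if tok.kind != "RANGE_DOTS":
                raise ParseError(f"expected '..' in RANGE, found {tok.value!r}", tok.line)
            hi = p.expect_number()
            p.expect_symbol(")")
            p.expect_symbol(";")
            domain = (lo, hi)
        elif p.at_keyword("TERM"):
            label, mf = _parse_term(p)
            if label in terms:
                raise ParseError(f"duplicate TERM {label!r} in variable {name!r}", name_tok.line)
            terms[label] = mf
        elif p.at_keyword(*_KEYWORDS_SKIP_LINE):
            p.skip_to_semicolon()
        else:
            tok = p.peek()
            raise ParseError(f"unexpected token {tok.value!r} in {name!r} block", tok.line)
    if domain is None:
        raise ParseError(f"variable {name!r}: missing RANGE declaration", name_tok.line)
    try:
        return name, LinguisticVariable(name, domain, terms)
    except ParameterError as exc:
        raise ParseError(str(exc), name_tok.line) from exc


def _parse_rule_expr(p: _Parser) -> Node:
    def factor() -> Node:
        tok = p.peek()
        if tok is not None and tok.value == "(":
            p.next()
            node = expr()
            p.expect_symbol(")")
            return node
        var = p.expect_ident().value
        p.expect_keyword("IS")
        cat = p.expect_ident().value
        return Atom(var, cat)

    def term() -> Node:
        nodes = [factor()]
        while p.at_keyword("AND"):
            p.next()
            nodes.append(factor())
        return nodes[0] if len(nodes) == 1 else BoolOp("and", tuple(nodes))

    def expr() -> Node:
        nodes = [term()]
        while p.at_keyword("OR"):
            p.next()
            nodes.append(term())
        return nodes[0] if len(nodes) == 1 else BoolOp("or", tuple(nodes))

    return expr()


def parse_rulebase(text: str) -> RuleBase:
    """Parse an FCL-style source into a :class:`RuleBase`.

    Raises :class:`ParseError` (with the offending line) on malformed
    syntax, duplicate rule numbers, or rules referencing undeclared
    variables or categories.
    """
    p = _Parser(_tokenize(text))
    p.expect_keyword("FUNCTION_BLOCK")
    p.expect_ident()
    declared_inputs: list[str] = []
    declared_outputs: list[str] = []
    variables: dict[str, LinguisticVariable] = {}
    rules: list[FuzzyRule] = []
    seen_numbers: set[int] = set()

    while True:
        if p.at_keyword("END_FUNCTION_BLOCK"):
            p.next()
            break
        if p.at_keyword("VAR_INPUT", "VAR_OUTPUT"):
            which = p.next().value.upper()
            target = declared_inputs if which == "VAR_INPUT" else declared_outputs
            while not p.at_keyword("END_VAR"):
                name = p.expect_ident().value
                p.expect_symbol(":")
                p.expect_keyword("REAL")
                p.expect_symbol(";")
                target.append(name)
            p.next()
        elif p.at_keyword("FUZZIFY"):
            p.next()
            name, lv = _parse_fuzzify_block(p, "END_FUZZIFY")
            variables[name] = lv
        elif p.at_keyword("DEFUZZIFY"):
            p.next()
            name, lv = _parse_fuzzify_block(p, "END_DEFUZZIFY")
            variables[name] = lv
        elif p.at_keyword("RULEBLOCK"):
            p.next()
            if p.peek() is not None and p.peek().kind == "IDENT" and not p.at_keyword("RULE", "END_RULEBLOCK", *_KEYWORDS_SKIP_LINE):
                p.next()  # optional rule-block name
            while not p.at_keyword("END_RULEBLOCK"):
                if p.at_keyword(*_KEYWORDS_SKIP_LINE):
                    p.skip_to_semicolon()
                    continue
                rule_tok = p.expect_keyword("RULE")
                number = int(p.expect_number())
                if number in seen_numbers:
                    raise ParseError(f"duplicate rule number {number}", rule_tok.line)
                seen_numbers.add(number)
                p.expect_symbol(":")
                p.expect_keyword("IF")
                antecedent = _parse_rule_expr(p)
                p.expect_keyword("THEN")
                out_var = p.expect_ident().value
                p.expect_keyword("IS")
                consequent = p.expect_ident().value
                p.expect_symbol(";")
                if declared_outputs and out_var != declared_outputs[0]:
                    raise ParseError(f"rule {number}: consequent variable {out_var!r} is not the output", rule_tok.line)
                rules.append(FuzzyRule(number, antecedent, consequent))
            p.next()
        else:
            tok = p.peek()
            raise ParseError(f"unexpected token {tok.value!r} at top level", tok.line)

    if len(declared_outputs) != 1:
        raise ParseError(f"exactly one output variable required, found {len(declared_outputs)}")
    output = declared_outputs[0]
    missing = [v for v in declared_inputs + declared_outputs if v not in variables]
    if missing:
        raise ParseError(f"declared variables without FUZZIFY/DEFUZZIFY blocks: {missing}")
    return RuleBase(variables, output, rules)


# -- serialization -------------------------------------------------------


def _mf_to_fcl(mf: MembershipFunction) -> str:
    kind, p = mf.kind, mf.params
    if kind == "sigmoid_increasing":
        return f"sigm {p[1]!r} {p[0]!r}"
    if kind == "sigmoid_decreasing":
        return f"sigm {-p[1]!r} {p[0]!r}"
    if kind == "gaussian":
        return f"gauss {p[0]!r} {p[1]!r}"
    if kind == "triangle":
        return f"trian {p[0]!r} {p[1]!r} {p[2]!r}"
    if kind == "trapezoid":
        return "trape " + " ".join("inf" if v == math.inf else "-inf" if v == -math.inf else repr(v) for v in p)
    if kind == "singleton":
        return f"singleton {p[0]!r} {p[1]!r}"
    raise ParameterError(f"unknown membership kind {kind!r}")


def _node_to_fcl(node: Node) -> str:
    if isinstance(node, Atom):
        return f"({node.var} IS {node.category})"
    joiner = " AND " if node.op == "and" else " OR "
    return "(" + joiner.join(_node_to_fcl(o) for o in node.operands) + ")"


def rulebase_to_fcl(rb: RuleBase, name: str = "gene_activity") -> str:
    """Serialize a rule base back to the FCL subset (round-trip safe)."""
    lines = [f"FUNCTION_BLOCK {name}", "", "VAR_INPUT"]
    for var in rb.input_names:
        lines.append(f"    {var} : REAL;")
    lines += ["END_VAR", "", "VAR_OUTPUT", f"    {rb.output} : REAL;", "END_VAR", ""]
    for var_name, lv in rb.variables.items():
        block = "DEFUZZIFY" if var_name == rb.output else "FUZZIFY"
        lines.append(f"{block} {var_name}")
        lo, hi = lv.domain
        lines.append(f"    RANGE := ({lo!r} .. {hi!r});")
        for label, mf in lv.categories.items():
            lines.append(f"    TERM {label} := {_mf_to_fcl(mf)};")
        if block == "DEFUZZIFY":
            lines.append("    METHOD : COG;")
        lines.append(f"END_{block}")
        lines.append("")
    lines.append("RULEBLOCK rules")
    lines += ["    AND : MIN;", "    OR : MAX;", "    ACT : MIN;", "    ACCU : MAX;"]
    for rule in rb.rules:
        lines.append(f"    RULE {rule.number}: IF {_node_to_fcl(rule.antecedent)} THEN {rb.output} IS {rule.consequent};")
    lines += ["END_RULEBLOCK", "", "END_FUNCTION_BLOCK", ""]
    return "\n".join(lines)
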