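"""Independent brute-force oracles used to cross-check the engine.

Everything here is deliberately written from the defining formulas with
plain Python loops (scalar math, no shared code with the package's
vectorized inference path) so it can serve as an independent reference.
"""

import math

import numpy as np

from fuzzyact.fuzzy import Atom


def mf_degree(mf, x: float) -> float:
    """Scalar membership degree, re-derived from the shape definitions."""
    kind, p = mf.kind, mf.params
    if kind == "sigmoid_increasing":
        c, a = p
        try:
            return 1.0 / (1.0 + math.exp(-a * (x - c)))
        except OverflowError:
            return 0.0 if x < c else 1.0
    if kind == "sigmoid_decreasing":
        c, a = p
        try:
            return 1.0 / (1.0 + math.exp(a * (x - c)))
        except OverflowError:
            return 1.0 if x < c else 0.0
    if kind == "gaussian":
        mu, sd = p
        return math.exp(-((x - mu) ** 2) / (2.0 * sd * sd))
    if kind == "triangle":
        a_, b_, c_ = p
        if x <= a_ or x >= c_:
            return 1.0 if (x == b_ == a_ or x == b_ == c_) else 0.0
        if x == b_:
            return 1.0
        if x < b_:
            return (x - a_) / (b_ - a_)
        return (c_ - x) / (c_ - b_)
    if kind == "trapezoid":
        a_, b_, c_, d_ = p
        if b_ <= x <= c_:
            return 1.0
        if x < b_:
            if not math.isfinite(a_) or x <= a_:
                return 0.0
            return (x - a_) / (b_ - a_)
        if not math.isfinite(d_) or x >= d_:
            return 0.0
        return (d_ - x) / (d_ - c_)
    if kind == "singleton":
        loc, tol = p
        return 1.0 if abs(x - loc) < tol else 0.0
    raise ValueError(kind)


def antecedent_degree(node, variables, inputs) -> float:
    """Recursive tree walk with scalar min/max semantics."""
    if isinstance(node, Atom):
        return mf_degree(variables[node.var].categories[node.category], float(inputs[node.var]))
    vals = [antecedent_degree(child, variables, inputs) for child in node.operands]
    return min(vals) if node.op == "and" else max(vals)


def brute_force_activations(rb, inputs) -> list:
    return [antecedent_degree(r.antecedent, rb.variables, inputs) for r in rb.rules]


def brute_force_aggregate(rb, activations, resolution=2001):
    """Clipped-union output curve built with explicit loops."""
    lo, hi = rb.variables[rb.output].domain
    xs = [lo + (hi - lo) * i / (resolution - 1) for i in range(resolution)]
    agg = [0.0] * resolution
    out_var = rb.variables[rb.output]
    for rule, act in zip(rb.rules, activations):
        mf = out_var.categories[rule.consequent]
        for i, x in enumerate(xs):
            clipped = min(act, mf_degree(mf, x))
            if clipped > agg[i]:
                agg[i] = clipped
    return xs, agg


def brute_force_defuzzify(rb, activations, resolution=2001) -> float:
    """Centroid via trapezoidal integration of the brute-force curve."""
    xs, agg = brute_force_aggregate(rb, activations, resolution)
    num = np.trapezoid([x * m for x, m in zip(xs, agg)], xs)
    den = np.trapezoid(agg, xs)
    return 0.0 if den == 0.0 else float(num / den)


def brute_force_infer(rb, inputs, resolution=2001) -> float:
    return brute_force_defuzzify(rb, brute_force_activations(rb, inputs), resolution)


def pairwise_auc(scores, labels) -> float:
    """AUC by direct positive/negative pair counting (ties at 0.5)."""
    scores = list(map(float, scores))
    labels = list(labels)
    classes = sorted(set(labels), key=repr)
    assert len(classes) == 2
    pos = [s for s, y in zip(scores, labels) if y == classes[1]]
    neg = [s for s, y in zip(scores, labels) if y == classes[0]]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))
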