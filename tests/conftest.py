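import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import fuzzyact as fa

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rb():
    """Shipped default 30-rule base."""
    return fa.load_default_rulebase()


@pytest.fixture(scope="session")
def sep_expr_values():
    """Expression vector with three tightly separated tertile clusters.

    Means (2, 8, 14) with within-group std 0.05: membership tails of the
    low/high sigmoids are numerically zero at the middle mean, so only the
    rules addressed by a single expression category fire.
    """
    rng = np.random.default_rng(42)
    vals = np.concatenate([
        rng.normal(2.0, 0.05, 40),
        rng.normal(8.0, 0.05, 40),
        rng.normal(14.0, 0.05, 40),
    ])
    rng.shuffle(vals)
    return vals


@pytest.fixture(scope="session")
def sep_expr_var(sep_expr_values):
    return fa.fit_expression_memberships(sep_expr_values, gene="SEP")


@pytest.fixture(scope="session")
def sep_expr_fit(sep_expr_values):
    return fa.fit_expression(sep_expr_values, gene="SEP")


def make_cohort(n_samples=30, genes=("G1", "G2"), variants=(), seed=0, sep_gene=None):
    """Small hand-rolled cohort with Gaussian expression and near-zero CN.

    ``sep_gene`` names one gene given three well-separated expression
    clusters (means 2/8/14) so its category memberships are crisp.
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i}" for i in range(n_samples)]
    expr = pd.DataFrame(rng.normal(8, 1, (len(genes), n_samples)), index=list(genes), columns=samples)
    if sep_gene is not None:
        groups = np.array_split(np.arange(n_samples), 3)
        for mean, idx in zip((2.0, 8.0, 14.0), groups):
            expr.loc[sep_gene, expr.columns[idx]] = rng.normal(mean, 0.05, idx.size)
    cn = pd.DataFrame(rng.normal(0, 0.05, (len(genes), n_samples)), index=list(genes), columns=samples)
    return fa.OmicsCohort(expr, cn, list(variants))
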