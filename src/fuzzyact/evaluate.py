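"""Drug-sensitivity evaluation utilities.

Three pieces of machinery validate activity scores against cell-line drug
response: (i) ROC-AUC of any per-sample score against binary sensitivity
calls (Mann-Whitney formulation, ties at 0.5); (ii) sensitivity calls from a
two-component Gaussian mixture on an ActArea-like metric, with the resistant
cutoff min(X, mu1+sigma1) and the sensitive cutoff max(X, mu2+sigma2) where
X is the intersection of the two weighted component densities; and (iii) a
paired bootstrap test on the difference of two AUCs measured on the same
samples. Fixed published thresholds (per-compound) are supported directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.mixture import GaussianMixture

from .errors import FitError, InputError, ParameterError

__all__ = [
    "roc_auc",
    "GmmThresholds",
    "gaussian_intersection",
    "gmm_sensitivity_calls",
    "bootstrap_auc_compare",
    "MetricThreshold",
    "CompoundConfig",
    "COMPOUND_TABLE",
    "fixed_threshold_calls",
]

DRUG_METRICS = ("ActArea", "IC50", "EC50", "Amax")


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    uniq = np.unique(y)
    if uniq.size != 2:
        raise InputError(f"labels must contain exactly two classes, found {uniq.tolist()}")
    return y


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve of ``scores`` against binary ``labels``.

    Equivalent to the Mann-Whitney U statistic scaled to [0, 1]; tied
    scores contribute 0.5 per positive-negative pair.
    """
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise InputError("scores and labels must have the same length")
    if not np.all(np.isfinite(s)):
        raise InputError("scores contain non-finite values")
    y_bin = (y == np.unique(y)[1]).astype(int)
    return float(roc_auc_score(y_bin, s))


def gaussian_intersection(mu1, sigma1, w1, mu2, sigma2, w2) -> float:
    """Intersection X of two weighted Gaussian densities inside (mu1, mu2).

    Solves w1*N(x|mu1,sigma1) = w2*N(x|mu2,sigma2). For equal variances the
    equation is linear; otherwise the root of the quadratic lying between
    the means is taken (clamped to [mu1, mu2] in degenerate weightings).
    """
    if mu1 > mu2:
        raise ParameterError(f"component means must be ordered, got {mu1} > {mu2}")
    if min(sigma1, sigma2) <= 0 or min(w1, w2) <= 0:
        raise ParameterError("component stds and weights must be > 0")
    if mu1 == mu2:
        return float(mu1)
    a = 0.5 * (1.0 / sigma2**2 - 1.0 / sigma1**2)
    b = mu1 / sigma1**2 - mu2 / sigma2**2
    c = 0.5 * (mu2**2 / sigma2**2 - mu1**2 / sigma1**2) + math.log((w1 * sigma2) / (w2 * sigma1))
    if abs(a) < 1e-14:
        x = -c / b
        return float(min(max(x, mu1), mu2))
    roots = np.roots([a, b, c])
    roots = roots[np.isreal(roots)].real
    if roots.size == 0:
        raise FitError("no real intersection between the two components")
    inside = roots[(roots >= mu1) & (roots <= mu2)]
    if inside.size:
        mid = 0.5 * (mu1 + mu2)
        x = inside[np.argmin(np.abs(inside - mid))]
    else:
        # extreme weight imbalance: clamp the nearest root into [mu1, mu2]
        x = roots[np.argmin(np.minimum(np.abs(roots - mu1), np.abs(roots - mu2)))]
        x = min(max(x, mu1), mu2)
    return float(x)


@dataclass(frozen=True)
class GmmThresholds:
    """Two-component mixture parameters and the derived call cutoffs."""

    mu1: float
    sigma1: float
    w1: float
    mu2: float
    sigma2: float
    w2: float
    X: float = field(init=False)
    resistant_cutoff: float = field(init=False)
    sensitive_cutoff: float = field(init=False)

    def __post_init__(self):
        X = gaussian_intersection(self.mu1, self.sigma1, self.w1, self.mu2, self.sigma2, self.w2)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "resistant_cutoff", min(X, self.mu1 + self.sigma1))
        object.__setattr__(self, "sensitive_cutoff", max(X, self.mu2 + self.sigma2))

    def call(self, values) -> np.ndarray:
        """Per-sample calls: resistant / intermediate / sensitive."""
        v = np.asarray(values, dtype=float)
        calls = np.full(v.shape, "intermediate", dtype=object)
        calls[v < self.resistant_cutoff] = "resistant"
        calls[v > self.sensitive_cutoff] = "sensitive"
        return calls


def gmm_sensitivity_calls(values, seed: int = 0):
    """Fit a two-component univariate mixture and call sensitivity classes.

    EM is initialized by a median split (components ordered by mean),
    run to tolerance 1e-8 with at most 200 iterations, deterministic given
    ``seed``. Returns ``(GmmThresholds, calls)``.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 20:
        raise InputError(f"need >= 20 finite values to fit the mixture, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise InputError("values contain non-finite entries")
    med = np.median(v)
    lower, upper = v[v <= med], v[v > med]
    if lower.size == 0 or upper.size == 0:
        raise FitError("degenerate value distribution; supply manual thresholds")
    means_init = np.array([[lower.mean()], [upper.mean()]])
    var_floor = max(v.var() * 1e-6, 1e-12)
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        max_iter=200,
        tol=1e-8,
        n_init=1,
        means_init=means_init,
        weights_init=np.array([lower.size, upper.size]) / v.size,
        random_state=int(seed),
        reg_covar=var_floor,
    )
    gm.fit(v.reshape(-1, 1))
    mus = gm.means_.ravel()
    sigmas = np.sqrt(gm.covariances_.ravel())
    ws = gm.weights_.ravel()
    order = np.argsort(mus)
    mus, sigmas, ws = mus[order], sigmas[order], ws[order]
    if min(ws) < 1e-3 or min(sigmas) <= 0:
        raise FitError(
            "mixture fit degenerated (vanishing component); supply manual thresholds"
        )
    thresholds = GmmThresholds(float(mus[0]), float(sigmas[0]), float(ws[0]),
                               float(mus[1]), float(sigmas[1]), float(ws[1]))
    return thresholds, thresholds.call(v)


def bootstrap_auc_compare(scores_a, scores_b, labels, n_boot: int = 2000, seed: int = 0) -> float:
    """Two-sided paired bootstrap p-value for AUC(a) = AUC(b).

    Samples are resampled with replacement within each label class
    (stratified), both scores re-evaluated on the same resample, and the
    observed AUC difference is compared with the bootstrap spread of the
    difference (normal approximation on D = diff / sd, as in standard
    paired-bootstrap ROC tests). Deterministic given ``seed``.
    """
    if n_boot < 1000:
        raise InputError(f"n_boot must be >= 1000, got {n_boot}")
    y = _check_labels(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not (a.shape == b.shape == y.shape):
        raise InputError("scores_a, scores_b and labels must be paired (same length)")
    observed = roc_auc(a, y) - roc_auc(b, y)
    if np.array_equal(a, b):
        return 1.0
    classes = np.unique(y)
    pos_idx = np.flatnonzero(y == classes[1])
    neg_idx = np.flatnonzero(y == classes[0])
    rng = np.random.default_rng(int(seed))
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        p = rng.choice(pos_idx, size=pos_idx.size, replace=True)
        n = rng.choice(neg_idx, size=neg_idx.size, replace=True)
        idx = np.concatenate([p, n])
        ys = y[idx]
        diffs[i] = roc_auc(a[idx], ys) - roc_auc(b[idx], ys)
    sd = float(np.std(diffs, ddof=1))
    if sd == 0.0:
        return 1.0 if observed == 0.0 else 0.0
    from scipy.stats import norm

    z = observed / sd
    return float(2.0 * norm.sf(abs(z)))


# -- fixed published thresholds ------------------------------------------


@dataclass(frozen=True)
class MetricThreshold:
    """One metric's sensitive/resistant cutoffs with comparison directions.

    ``sensitive_op``/``resistant_op`` are comparison operators applied as
    ``value <op> cutoff`` (one of '<=', '>=', '<', '>').
    """

    metric: str
    sensitive_op: str
    sensitive_value: float
    resistant_op: str
    resistant_value: float

    _OPS = {"<=": np.less_equal, ">=": np.greater_equal, "<": np.less, ">": np.greater}

    def __post_init__(self):
        if self.metric not in DRUG_METRICS:
            raise ParameterError(f"unknown drug metric {self.metric!r}")
        for op in (self.sensitive_op, self.resistant_op):
            if op not in self._OPS:
                raise ParameterError(f"unknown comparison operator {op!r}")

    def sensitive(self, value) -> bool:
        return bool(self._OPS[self.sensitive_op](value, self.sensitive_value))

    def resistant(self, value) -> bool:
        return bool(self._OPS[self.resistant_op](value, self.resistant_value))


@dataclass(frozen=True)
class CompoundConfig:
    """A targeted compound, its driver-gene predictors and call thresholds.

    When several metric thresholds are listed, a sample is called sensitive
    only if every metric's sensitive condition holds, and resistant if any
    metric's resistant condition holds (combined criteria like EC50 + Amax).
    """

    name: str
    targets: tuple
    predictors: tuple
    thresholds: tuple

    def call(self, metrics: dict) -> str:
        try:
            sens = all(t.sensitive(metrics[t.metric]) for t in self.thresholds)
            res = any(t.resistant(metrics[t.metric]) for t in self.thresholds)
        except KeyError as exc:
            raise InputError(f"{self.name}: missing metric {exc.args[0]!r}") from None
        if sens and not res:
            return "sensitive"
        if res and not sens:
            return "resistant"
        return "intermediate"


#: Published per-compound sensitivity/resistance thresholds.
COMPOUND_TABLE = {
    "PLX4720": CompoundConfig(
        "PLX4720", ("BRAF",), ("BRAF",),
        (MetricThreshold("ActArea", ">=", 2.05, "<=", 0.47),),
    ),
    "AZD6244": CompoundConfig(
        "AZD6244", ("MEK",), ("BRAF",),
        (MetricThreshold("ActArea", ">=", 3.02, "<=", 0.69),),
    ),
    "Erlotinib": CompoundConfig(
        "Erlotinib", ("EGFR",), ("EGFR", "KRAS"),
        (MetricThreshold("ActArea", ">=", 1.74, "<=", 0.42),),
    ),
    "Nutlin-3": CompoundConfig(
        "Nutlin-3", ("MDM2",), ("TP53",),
        (MetricThreshold("IC50", "<=", 4.26, ">=", 6.94),),
    ),
    "BYL719": CompoundConfig(
        "BYL719", ("PIK3CA",), ("PIK3CA", "PTEN"),
        (
            MetricThreshold("EC50", "<=", 3.04, ">", 3.04),
            MetricThreshold("Amax", "<=", -30.0, ">", -30.0),
        ),
    ),
}


def fixed_threshold_calls(responses: pd.DataFrame, compound: CompoundConfig) -> pd.Series:
    """Apply a compound's published thresholds to a long-format response table.

    ``responses`` must have columns sample, metric, value (one value per
    sample per metric). Returns a sample-indexed Series of calls.
    """
    required = {"sample", "metric", "value"}
    if not required.issubset(responses.columns):
        raise InputError(f"response table needs columns {sorted(required)}")
    wide = responses.pivot_table(index="sample", columns="metric", values="value", aggfunc="first")
    calls = {}
    for sample, row in wide.iterrows():
        calls[sample] = compound.call(row.dropna().to_dict())
    return pd.Series(calls, name="call")
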