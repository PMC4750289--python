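"""Data-driven construction of the four input linguistic variables.

Expression categories are fitted per gene from the cohort: samples are
split into three rank-based tertile groups; the *medium* category is a
Gaussian at the middle group's mean/std and *low*/*high* are sigmoids
inflecting at the outer groups' means, with slopes matched to each group's
std via ``slope_from_std``. Copy-number categories are fixed shapes on the
log2 copy-ratio scale. Mutations are a categorical variable over eight
MAF-style classes plus ``No_Mutation``, and a variant is *recurrent* when
strictly more than a configurable fraction (default 1%) of cohort samples
carry a variant at the same position.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace

import numpy as np

from .cohort import VariantRecord
from .errors import DegenerateInputError, InputError, ParameterError
from .fuzzy import LinguisticVariable, MembershipFunction, slope_from_std

logger = logging.getLogger(__name__)

__all__ = [
    "MUTATION_CLASSES",
    "NO_MUTATION",
    "MUTATION_CODES",
    "ACTIVATING_CLASSES",
    "TRUNCATING_CLASSES",
    "ExpressionFit",
    "RecurrenceConfig",
    "fit_expression_memberships",
    "fit_expression",
    "default_cn_variable",
    "mutation_variable",
    "recurrence_variable",
    "compute_recurrence",
]

#: The eight modeled mutation-type classes, in encoding order.
MUTATION_CLASSES = (
    "Missense_Mutation",
    "In_Frame_Ins",
    "In_Frame_Del",
    "Nonsense_Mutation",
    "Nonstop_Mutation",
    "Frame_Shift_Ins",
    "Frame_Shift_Del",
    "Splice_Site",
)

NO_MUTATION = "No_Mutation"

#: Integer codes used to fuzzify the categorical mutation variable.
MUTATION_CODES = {name: i for i, name in enumerate(MUTATION_CLASSES + (NO_MUTATION,))}

#: Classes whose (recurrent) presence may indicate a gain of function.
ACTIVATING_CLASSES = frozenset({"Missense_Mutation", "In_Frame_Ins", "In_Frame_Del"})

#: Protein-truncating classes indicating a loss of function.
TRUNCATING_CLASSES = frozenset(
    {"Nonsense_Mutation", "Nonstop_Mutation", "Frame_Shift_Ins", "Frame_Shift_Del", "Splice_Site"}
)

#: Relative floor applied to tertile stds, as a fraction of the observed range.
STD_FLOOR_FRACTION = 1e-3

#: Domain padding around the observed expression range, in units of s_med.
DOMAIN_PAD_STDS = 3.0


@dataclass(frozen=True)
class ExpressionFit:
    """Tertile summary of one gene's expression distribution."""

    gene: str
    m_low: float
    m_med: float
    m_high: float
    s_low: float
    s_med: float
    s_high: float

    def __post_init__(self):
        if not (self.m_low <= self.m_med <= self.m_high):
            raise ParameterError(f"{self.gene}: tertile means must be ordered, got "
                                 f"({self.m_low}, {self.m_med}, {self.m_high})")
        if min(self.s_low, self.s_med, self.s_high) <= 0:
            raise ParameterError(f"{self.gene}: tertile stds must be > 0")

    def to_variable(self, name: str = "Expression", observed_range: tuple | None = None) -> LinguisticVariable:
        """Build the low/medium/high linguistic variable from the fit."""
        if observed_range is None:
            lo, hi = self.m_low, self.m_high
        else:
            lo, hi = observed_range
        pad = DOMAIN_PAD_STDS * self.s_med
        return LinguisticVariable(
            name,
            (lo - pad, hi + pad),
            {
                "low": MembershipFunction.sigmoid_decreasing(self.m_low, slope_from_std(self.s_low)),
                "medium": MembershipFunction.gaussian(self.m_med, self.s_med),
                "high": MembershipFunction.sigmoid_increasing(self.m_high, slope_from_std(self.s_high)),
            },
        )


def _tertile_groups(values: np.ndarray) -> list[np.ndarray]:
    """Split values into three rank-ordered groups, as evenly as possible.

    Ties are broken by stable input order; when n is not divisible by 3 the
    earlier (lower-rank) groups take the extra members.
    """
    order = np.argsort(values, kind="stable")
    return [values[idx] for idx in np.array_split(order, 3)]


def fit_expression(values, gene: str = "gene") -> ExpressionFit:
    """Tertile means/stds of one gene's per-sample expression vector."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise InputError(f"{gene}: expected a 1-D expression vector")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{gene}: expression vector contains non-finite values")
    if arr.size < 6:
        raise InputError(f"{gene}: need >= 6 samples to fit tertiles, got {arr.size}")
    if np.unique(arr).size < 3:
        if np.unique(arr).size == 1:
            raise DegenerateInputError(f"{gene}: constant expression vector")
        raise InputError(f"{gene}: need >= 3 distinct expression values")
    span = float(arr.max() - arr.min())
    floor = STD_FLOOR_FRACTION * span
    groups = _tertile_groups(arr)
    means = [float(np.mean(g)) for g in groups]
    stds = [max(float(np.std(g, ddof=0)), floor) for g in groups]
    return ExpressionFit(gene, means[0], means[1], means[2], stds[0], stds[1], stds[2])


def fit_expression_memberships(values, gene: str = "gene", name: str = "Expression") -> LinguisticVariable:
    """Fit the per-gene low/medium/high expression variable.

    The domain is the observed value range padded by 3 * s_med on each side.
    Raises :class:`DegenerateInputError` for a constant vector and
    :class:`InputError` for too few (or too few distinct) samples.
    """
    arr = np.asarray(values, dtype=float)
    fit = fit_expression(arr, gene=gene)
    return fit.to_variable(name=name, observed_range=(float(arr.min()), float(arr.max())))


def default_cn_variable(
    name: str = "CN",
    loss_plateau: float = -0.6,
    loss_zero: float = -0.2,
    gain_zero: float = 0.2,
    gain_plateau: float = 0.6,
    neutral_halfwidth: float = 0.4,
    domain: tuple = (-3.0, 3.0),
) -> LinguisticVariable:
    """Fixed copy-number variable on the log2 copy-ratio scale.

    *deleted* is fully on at ratios <= ``loss_plateau`` and off beyond
    ``loss_zero``; *amplified* mirrors it on the gain side; *neutral* is a
    triangle peaking at 0. The default +-0.2 / +-0.6 breakpoints are the
    conventional SNP-array shallow/deep gain-loss cutoffs.
    """
    if not (loss_plateau < loss_zero <= 0 <= gain_zero < gain_plateau):
        raise ParameterError("copy-number breakpoints must satisfy loss_plateau < loss_zero <= 0 <= gain_zero < gain_plateau")
    return LinguisticVariable(
        name,
        domain,
        {
            "deleted": MembershipFunction.trapezoid(-np.inf, -np.inf, loss_plateau, loss_zero),
            "neutral": MembershipFunction.triangle(-neutral_halfwidth, 0.0, neutral_halfwidth),
            "amplified": MembershipFunction.trapezoid(gain_zero, gain_plateau, np.inf, np.inf),
        },
    )


def mutation_variable(name: str = "Mutation") -> LinguisticVariable:
    """Categorical mutation-class variable on integer codes (singletons)."""
    return LinguisticVariable(
        name,
        (-0.5, len(MUTATION_CODES) - 0.5),
        {cls: MembershipFunction.singleton(code) for cls, code in MUTATION_CODES.items()},
    )


def recurrence_variable(name: str = "Recurrence") -> LinguisticVariable:
    """Binary recurrence variable: non_recurrent = 0, recurrent = 1."""
    return LinguisticVariable(
        name,
        (-0.5, 1.5),
        {
            "non_recurrent": MembershipFunction.singleton(0.0),
            "recurrent": MembershipFunction.singleton(1.0),
        },
    )


@dataclass(frozen=True)
class RecurrenceConfig:
    """Recurrence calling parameters.

    A variant is recurrent when strictly more than ``threshold_fraction`` of
    cohort samples carry a variant at the same position. ``position_mode``
    selects the preferred coordinate system; records lacking it fall back to
    the other one.
    """

    threshold_fraction: float = 0.01
    position_mode: str = "protein"

    def __post_init__(self):
        if not (0.0 < self.threshold_fraction < 1.0):
            raise ParameterError(f"threshold_fraction must be in (0, 1), got {self.threshold_fraction}")
        if self.position_mode not in ("protein", "genomic"):
            raise ParameterError(f"position_mode must be 'protein' or 'genomic', got {self.position_mode!r}")


def compute_recurrence(variants, n_samples: int, cfg: RecurrenceConfig | None = None) -> list:
    """Flag each variant as recurrent or not.

    For every (gene, position) pair the number of *distinct* samples carrying
    any variant there is counted; all variants at that position are flagged
    recurrent iff count / n_samples > threshold (strict). Variants whose
    position cannot be resolved are flagged non-recurrent with a warning.
    Returns a new list of records in input order.
    """
    if n_samples < 1:
        raise InputError(f"n_samples must be >= 1, got {n_samples}")
    cfg = cfg or RecurrenceConfig()

    def resolve(v: VariantRecord):
        protein = ("protein", int(v.protein_position)) if v.protein_position is not None else None
        genomic = ("genomic", tuple(v.genomic_position)) if v.genomic_position is not None else None
        if cfg.position_mode == "genomic":
            return genomic if genomic is not None else protein
        return protein if protein is not None else genomic

    carriers: dict = defaultdict(set)
    keys = []
    n_unresolved = 0
    for v in variants:
        key = resolve(v)
        if key is None and v.mutation_class != NO_MUTATION:
            n_unresolved += 1
        keys.append(key)
        if key is not None:
            carriers[(v.gene, key)].add(v.sample_id)
    if n_unresolved:
        logger.warning("%d variants with unresolvable positions flagged non_recurrent", n_unresolved)
    out = []
    threshold = cfg.threshold_fraction
    for v, key in zip(variants, keys):
        if key is None:
            flag = False
        else:
            flag = len(carriers[(v.gene, key)]) / n_samples > threshold
        out.append(replace(v, recurrent=flag))
    return out
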