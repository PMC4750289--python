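"""Applying the rule base to variants and whole cohorts.

Each variant is fuzzified as (mutation class, recurrence flag, the carrying
sample's expression, the carrying sample's copy number) and pushed through
the rule base; the centroid of the aggregated output is the variant's
activity score in [-1, 1]. Per gene x sample, the GoF score is the maximum
over positively-scoring variants (floored at 0) and the LoF score the
minimum over negatively-scoring variants (capped at 0); unmutated pairs are
scored once through the no-mutation rules and sign-split the same way.

Genes with a dominant-negative idiom (TP53 by default) use a mirrored rule
base in which every activating-mutation rule's consequent is reflected onto
its LoF counterpart, so a recurrent missense hotspot reads as a loss of
function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .cohort import OmicsCohort, VariantRecord
from .errors import DegenerateInputError, InputError
from .fuzzy import (
    DEFAULT_RESOLUTION,
    FuzzyRule,
    LinguisticVariable,
    RuleBase,
    aggregate_and_defuzzify,
    fire_rules,
    parse_rulebase,
)
from .memberships import (
    ACTIVATING_CLASSES,
    MUTATION_CODES,
    NO_MUTATION,
    RecurrenceConfig,
    compute_recurrence,
    fit_expression_memberships,
)

logger = logging.getLogger(__name__)

__all__ = [
    "load_default_rulebase",
    "DEFAULT_SPECIAL_GENES",
    "SpecialRuleMap",
    "mirror_consequents",
    "apply_special_rules",
    "score_variant",
    "score_gene_sample",
    "score_cohort",
]

#: Consequent reflection used for dominant-negative (TP53-like) genes and
#: for the fully mirrored rule base.
MIRROR_MAP = {
    "high_GoF": "high_LoF",
    "GoF": "LoF",
    "low_GoF": "low_LoF",
    "no_effect": "no_effect",
    "low_LoF": "low_GoF",
    "LoF": "GoF",
    "high_LoF": "high_GoF",
}

DEFAULT_SPECIAL_GENES = frozenset({"TP53"})


def load_default_rulebase() -> RuleBase:
    """Parse and return the shipped 30-rule default rule base."""
    text = resources.files("fuzzyact").joinpath("data/default_rules.fcl").read_text()
    return parse_rulebase(text)


def _rule_mentions_classes(rule: FuzzyRule, classes, mutation_var: str = "Mutation") -> bool:
    return any(a.var == mutation_var and a.category in classes for a in rule.atoms())


def mirror_consequents(rb: RuleBase, only_activating: bool = False) -> RuleBase:
    """Reflect rule consequents through the GoF/LoF mirror map.

    With ``only_activating=True`` only rules whose antecedent mentions an
    activating mutation class (missense / in-frame indel) are reflected;
    this is the dominant-negative remapping. Without it every rule is
    reflected, which (under symmetric output categories) negates all scores.
    """
    new_rules = []
    for rule in rb.rules:
        if only_activating and not _rule_mentions_classes(rule, ACTIVATING_CLASSES):
            new_rules.append(rule)
        else:
            new_rules.append(FuzzyRule(rule.number, rule.antecedent, MIRROR_MAP[rule.consequent]))
    return RuleBase(dict(rb.variables), rb.output, new_rules)


@dataclass(frozen=True)
class SpecialRuleMap:
    """Per-gene rule-base lookup: mirrored for special genes, default else."""

    default: RuleBase
    special: RuleBase
    genes: frozenset

    def for_gene(self, gene: str) -> RuleBase:
        return self.special if gene in self.genes else self.default


def apply_special_rules(rb: RuleBase, special_genes=DEFAULT_SPECIAL_GENES) -> SpecialRuleMap:
    """Build the per-gene rule-base map with the dominant-negative remapping.

    For genes in ``special_genes`` (default {TP53}) every activating-mutation
    rule's consequent is mirrored to its LoF counterpart; all other rules,
    and all other genes, are untouched.
    """
    return SpecialRuleMap(rb, mirror_consequents(rb, only_activating=True), frozenset(special_genes))


def _variant_inputs(mutation_class: str, recurrent: bool, expr_value, cn_value) -> dict:
    try:
        code = MUTATION_CODES[mutation_class]
    except KeyError:
        raise InputError(f"unknown mutation class {mutation_class!r}") from None
    return {
        "Mutation": float(code),
        "Recurrence": 1.0 if recurrent else 0.0,
        "Expression": expr_value,
        "CN": cn_value,
    }


def score_variant(
    rb: RuleBase,
    variant: VariantRecord,
    expr_value: float,
    cn_value: float,
    expr_var: LinguisticVariable,
    cn_var: LinguisticVariable | None = None,
    resolution: int = DEFAULT_RESOLUTION,
) -> float:
    """Activity score of a single variant given its sample's omics values.

    ``expr_var`` is the gene's fitted expression variable; it replaces the
    placeholder Expression variable of ``rb``. ``cn_var`` optionally
    overrides the copy-number variable.
    """
    rb2 = rb.replace_variable(expr_var)
    if cn_var is not None:
        rb2 = rb2.replace_variable(cn_var)
    inputs = _variant_inputs(variant.mutation_class, variant.recurrent, float(expr_value), float(cn_value))
    return aggregate_and_defuzzify(rb2, fire_rules(rb2, inputs), resolution)


def score_gene_sample(variant_scores, no_mutation_score: float | None = None) -> tuple:
    """Fold variant scores into the (gof, lof) pair for one gene x sample.

    gof = max(0, max(scores)); lof = min(0, min(scores)). An unmutated pair
    supplies its single no-mutation score instead, sign-split the same way.
    """
    scores = [float(s) for s in variant_scores]
    if not scores:
        if no_mutation_score is None:
            raise InputError("no variant scores and no no-mutation score supplied")
        scores = [float(no_mutation_score)]
    return max(0.0, max(scores)), min(0.0, min(scores))


def _dedup_variants(variants) -> list:
    """Drop repeated (sample, gene, class, position) rows (MAF duplicates)."""
    seen = set()
    out = []
    for v in variants:
        key = (v.sample_id, v.gene, v.mutation_class, v.protein_position, v.genomic_position)
        if key not in seen:
            seen.add(key)
            out.append(v)
    return out


def score_cohort(
    cohort: OmicsCohort,
    rb: RuleBase | None = None,
    recurrence_cfg: RecurrenceConfig | None = None,
    special_genes=DEFAULT_SPECIAL_GENES,
    resolution: int = DEFAULT_RESOLUTION,
):
    """Score every gene x sample pair of a cohort.

    Fits the expression variable per gene, flags variant recurrence, scores
    every deduplicated variant, and scores unmutated pairs through the
    no-mutation rules. Returns ``(gof, lof)`` DataFrames (genes x samples);
    genes whose expression cannot be fitted (constant vector) are logged and
    reported as all-NaN rows.
    """
    rb = rb if rb is not None else load_default_rulebase()
    cfg = recurrence_cfg or RecurrenceConfig()
    genes, samples = cohort.genes, cohort.samples
    n_samples = cohort.n_samples

    raw = _dedup_variants(cohort.variants)
    n_dropped = len(cohort.variants) - len(raw)
    if n_dropped:
        logger.info("deduplicated %d repeated variant rows", n_dropped)
    real = [v for v in raw if v.mutation_class != NO_MUTATION]
    logger.info("scoring %d variants (%d silent/no-mutation records set aside)", len(real), len(raw) - len(real))
    flagged = compute_recurrence(real, n_samples, cfg)
    logger.info("recurrence-flagged %d of %d variants", sum(v.recurrent for v in flagged), len(flagged))

    by_gene: dict = {}
    for v in flagged:
        by_gene.setdefault(v.gene, []).append(v)

    rulemap = apply_special_rules(rb, frozenset(special_genes))
    sample_pos = {s: i for i, s in enumerate(samples)}
    gof = np.zeros((len(genes), len(samples)))
    lof = np.zeros((len(genes), len(samples)))
    expr_mat = cohort.expression.to_numpy(dtype=float)
    cn_mat = cohort.copy_number.to_numpy(dtype=float)
    n_skipped = 0

    for gi, gene in enumerate(genes):
        expr_vec = expr_mat[gi]
        cn_vec = cn_mat[gi]
        try:
            expr_var = fit_expression_memberships(expr_vec, gene=gene)
        except DegenerateInputError as exc:
            logger.warning("skipping gene %s: %s", gene, exc)
            gof[gi], lof[gi] = np.nan, np.nan
            n_skipped += 1
            continue
        grb = rulemap.for_gene(gene).replace_variable(expr_var)

        gene_variants = by_gene.get(gene, [])
        mutated_cols = np.zeros(len(samples), dtype=bool)
        if gene_variants:
            cols = np.array([sample_pos[v.sample_id] for v in gene_variants])
            mutated_cols[cols] = True
            inputs = {
                "Mutation": np.array([float(MUTATION_CODES[v.mutation_class]) for v in gene_variants]),
                "Recurrence": np.array([1.0 if v.recurrent else 0.0 for v in gene_variants]),
                "Expression": expr_vec[cols],
                "CN": cn_vec[cols],
            }
            vscores = aggregate_and_defuzzify(grb, fire_rules(grb, inputs), resolution)
            per_sample: dict = {}
            for col, s in zip(cols, np.atleast_1d(vscores)):
                per_sample.setdefault(col, []).append(float(s))
            for col, scores in per_sample.items():
                gof[gi, col], lof[gi, col] = score_gene_sample(scores)

        unmut = np.flatnonzero(~mutated_cols)
        if unmut.size:
            inputs = {
                "Mutation": np.full(unmut.size, float(MUTATION_CODES[NO_MUTATION])),
                "Recurrence": np.zeros(unmut.size),
                "Expression": expr_vec[unmut],
                "CN": cn_vec[unmut],
            }
            s = np.atleast_1d(aggregate_and_defuzzify(grb, fire_rules(grb, inputs), resolution))
            gof[gi, unmut] = np.maximum(0.0, s)
            lof[gi, unmut] = np.minimum(0.0, s)

    if n_skipped:
        logger.warning("%d genes skipped (constant expression)", n_skipped)
    gof_df = pd.DataFrame(gof, index=cohort.expression.index, columns=cohort.expression.columns)
    lof_df = pd.DataFrame(lof, index=cohort.expression.index, columns=cohort.expression.columns)
    return gof_df, lof_df
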