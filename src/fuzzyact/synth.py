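"""Seeded synthetic cohort generator.

Emulates the structure of a cell-line panel with matched exome, expression
and copy-number profiles: per-gene Gaussian background expression, log2
copy-ratio noise around zero, and planted driver genes. Oncogenes carry a
recurrent missense hotspot with raised expression and copy number in
mutants; tumor suppressors carry protein-truncating variants with lowered
expression and copy number; TP53-like "special" suppressors carry a
recurrent missense hotspot with raised expression (stabilized mutant
protein) and neutral copy number, so the mirrored rules read them as loss
of function. Neutral genes receive sparse non-recurrent passenger
missense variants. An optional drug-response table couples ActArea to the
mutation status of a designated driver gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import OmicsCohort, VariantRecord
from .errors import ParameterError

__all__ = ["SynthConfig", "SimulatedCohort", "generate_cohort", "special_genes_from_truth"]

ROLES = ("oncogene", "tsg", "special_tsg", "neutral")

#: Shared hotspot protein position used by every planted hotspot gene.
HOTSPOT_POSITION = 600

#: Range of passenger / non-hotspot protein positions.
POSITION_RANGE = (1, 500)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one simulated cohort.

    Effect sizes: ``delta_expr`` shifts mutant expression in units of the
    gene's own std; ``delta_cn`` shifts mutant log2 copy ratio;
    ``hotspot_concentration`` is the fraction of a hotspot gene's mutants
    sharing the single hotspot position; ``p_mut`` the fraction of samples
    mutated per driver; ``passenger_rate`` the per-sample chance of a
    passenger variant in a neutral gene. ``beta`` couples the response
    driver's mutation indicator to ActArea with Gaussian noise
    ``response_noise_sd``.
    """

    n_samples: int = 300
    n_genes: int = 50
    n_oncogenes: int = 5
    n_tsgs: int = 5
    n_special_tsgs: int = 0
    seed: int = 0
    p_mut: float = 0.2
    hotspot_concentration: float = 0.8
    delta_expr: float = 1.5
    delta_cn: float = 0.5
    passenger_rate: float = 0.01
    expr_mean_range: tuple = (4.0, 12.0)
    expr_std_range: tuple = (0.5, 1.5)
    cn_noise_sd: float = 0.15
    beta: float = 2.5
    response_noise_sd: float = 0.6
    with_response: bool = True

    def __post_init__(self):
        if self.n_samples < 30:
            raise ParameterError(f"n_samples must be >= 30 for tertile fitting, got {self.n_samples}")
        n_drivers = self.n_oncogenes + self.n_tsgs + self.n_special_tsgs
        if n_drivers > self.n_genes:
            raise ParameterError("more planted drivers than genes")
        if not 0.0 <= self.p_mut < 1.0:
            raise ParameterError(f"p_mut must be in [0, 1), got {self.p_mut}")
        if not 0.0 <= self.hotspot_concentration <= 1.0:
            raise ParameterError(f"hotspot_concentration must be in [0, 1], got {self.hotspot_concentration}")
        if not 0.0 <= self.passenger_rate < 1.0:
            raise ParameterError(f"passenger_rate must be in [0, 1), got {self.passenger_rate}")
        if self.expr_mean_range[0] >= self.expr_mean_range[1] or self.expr_std_range[0] <= 0:
            raise ParameterError("invalid expression background ranges")
        if self.cn_noise_sd <= 0 or self.response_noise_sd <= 0:
            raise ParameterError("noise standard deviations must be > 0")


@dataclass
class SimulatedCohort:
    """Generated cohort plus ground truth and optional drug response."""

    cohort: OmicsCohort
    truth: pd.DataFrame  # columns: gene, role
    response: pd.DataFrame | None = None
    config: SynthConfig = field(default_factory=SynthConfig)


def special_genes_from_truth(truth: pd.DataFrame) -> frozenset:
    """Genes whose planted role is the TP53-like dominant-negative idiom."""
    return frozenset(truth.loc[truth["role"] == "special_tsg", "gene"])


def _gene_names(cfg: SynthConfig) -> tuple[list, list]:
    roles = (
        ["oncogene"] * cfg.n_oncogenes
        + ["tsg"] * cfg.n_tsgs
        + ["special_tsg"] * cfg.n_special_tsgs
    )
    roles += ["neutral"] * (cfg.n_genes - len(roles))
    counters = {r: 0 for r in ROLES}
    prefixes = {"oncogene": "ONC", "tsg": "TSG", "special_tsg": "SPT", "neutral": "NEU"}
    names = []
    for role in roles:
        counters[role] += 1
        names.append(f"{prefixes[role]}{counters[role]:03d}")
    return names, roles


TRUNCATING_CHOICES = ("Nonsense_Mutation", "Frame_Shift_Del", "Frame_Shift_Ins", "Splice_Site")


def generate_cohort(cfg: SynthConfig | None = None) -> SimulatedCohort:
    """Generate a cohort deterministically from ``cfg`` (and its seed)."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    samples = [f"S{i:04d}" for i in range(1, cfg.n_samples + 1)]
    genes, roles = _gene_names(cfg)

    expr_means = rng.uniform(*cfg.expr_mean_range, size=cfg.n_genes)
    expr_stds = rng.uniform(*cfg.expr_std_range, size=cfg.n_genes)
    expression = rng.normal(expr_means[:, None], expr_stds[:, None], size=(cfg.n_genes, cfg.n_samples))
    copy_number = rng.normal(0.0, cfg.cn_noise_sd, size=(cfg.n_genes, cfg.n_samples))

    variants: list = []
    driver_mutants: dict = {}
    lo_pos, hi_pos = POSITION_RANGE

    for gi, (gene, role) in enumerate(zip(genes, roles)):
        if role == "neutral":
            hit = np.flatnonzero(rng.random(cfg.n_samples) < cfg.passenger_rate)
            for si in hit:
                pos = int(rng.integers(lo_pos, hi_pos + 1))
                variants.append(VariantRecord(samples[si], gene, "Missense_Mutation", protein_position=pos))
            continue
        n_mut = int(round(cfg.p_mut * cfg.n_samples))
        if n_mut == 0:
            continue
        mutant_idx = rng.choice(cfg.n_samples, size=n_mut, replace=False)
        driver_mutants[gene] = set(mutant_idx.tolist())
        n_hot = int(round(cfg.hotspot_concentration * n_mut))
        hot_flags = np.zeros(n_mut, dtype=bool)
        hot_flags[rng.choice(n_mut, size=n_hot, replace=False)] = True
        for flag_hot, si in zip(hot_flags, mutant_idx):
            if role in ("oncogene", "special_tsg"):
                cls = "Missense_Mutation"
                pos = HOTSPOT_POSITION if flag_hot else int(rng.integers(lo_pos, hi_pos + 1))
            else:  # tsg: truncating variants along the gene body
                cls = str(rng.choice(TRUNCATING_CHOICES))
                pos = int(rng.integers(lo_pos, hi_pos + 1))
            variants.append(VariantRecord(samples[si], gene, cls, protein_position=pos))
        shift = cfg.delta_expr * expr_stds[gi]
        if role == "oncogene":
            expression[gi, mutant_idx] += shift
            copy_number[gi, mutant_idx] += cfg.delta_cn
        elif role == "tsg":
            expression[gi, mutant_idx] -= shift
            copy_number[gi, mutant_idx] -= cfg.delta_cn
        else:  # special_tsg: stabilized mutant protein, neutral copy number
            expression[gi, mutant_idx] += shift

    expr_df = pd.DataFrame(expression, index=genes, columns=samples)
    cn_df = pd.DataFrame(copy_number, index=genes, columns=samples)
    cohort = OmicsCohort(expr_df, cn_df, variants)
    truth = pd.DataFrame({"gene": genes, "role": roles})

    response = None
    if cfg.with_response:
        driver = next((g for g, r in zip(genes, roles) if r == "oncogene"), None)
        if driver is None:
            driver = next((g for g, r in zip(genes, roles) if r != "neutral"), None)
        indicator = np.zeros(cfg.n_samples)
        if driver is not None:
            idx = sorted(driver_mutants.get(driver, ()))
            indicator[idx] = 1.0
        act_area = cfg.beta * indicator + rng.normal(0.0, cfg.response_noise_sd, size=cfg.n_samples)
        response = pd.DataFrame({"sample": samples, "metric": "ActArea", "value": act_area})

    return SimulatedCohort(cohort, truth, response, cfg)
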