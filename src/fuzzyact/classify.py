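"""Gene-level GoF/LoF labeling from per-sample activity matrices.

A gene is considered for classification only when it is mutated (carries at
least one non-silent variant) in strictly more than ``min_mut_fraction`` of
cohort samples. Among its mutated samples, the GoF gene score is the
fraction with gof > |lof| and the LoF gene score the fraction with
|lof| > gof (strict inequalities; ties count toward neither). The gene is
labeled GoF or LoF when the corresponding fraction exceeds 50%, and
``unclassified`` otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .memberships import NO_MUTATION

logger = logging.getLogger(__name__)

__all__ = ["GeneLabel", "classify_genes", "labels_to_frame"]

LABEL_COLUMNS = ["gene", "status", "gof_gene_score", "lof_gene_score", "n_mutated_samples"]


@dataclass(frozen=True)
class GeneLabel:
    gene: str
    status: str  # "GoF" | "LoF" | "unclassified"
    gof_gene_score: float
    lof_gene_score: float
    n_mutated_samples: int

    def __post_init__(self):
        if self.status not in ("GoF", "LoF", "unclassified"):
            raise InputError(f"invalid status {self.status!r}")


def classify_genes(
    gof: pd.DataFrame,
    lof: pd.DataFrame,
    variants,
    n_samples: int | None = None,
    min_mut_fraction: float = 0.01,
) -> list:
    """Label genes as oncogene-like (GoF) or tumor-suppressor-like (LoF).

    ``gof``/``lof`` are genes x samples matrices from ``score_cohort``;
    ``variants`` the cohort's variant records (silent/no-mutation records do
    not make a sample "mutated"). Genes failing the strict mutation-frequency
    filter are omitted; the omitted count is logged.
    """
    if not gof.index.equals(lof.index) or not gof.columns.equals(lof.columns):
        raise InputError("gof and lof matrices must share index and columns")
    n_samples = int(n_samples) if n_samples is not None else gof.shape[1]
    if n_samples < 1:
        raise InputError("n_samples must be >= 1")

    mutated: dict = {}
    for v in variants:
        if v.mutation_class == NO_MUTATION:
            continue
        if v.gene in gof.index:
            mutated.setdefault(v.gene, set()).add(v.sample_id)

    labels = []
    n_omitted = 0
    col_pos = {s: i for i, s in enumerate(gof.columns)}
    gof_mat = gof.to_numpy(dtype=float)
    lof_mat = lof.to_numpy(dtype=float)
    row_pos = {g: i for i, g in enumerate(gof.index)}
    for gene, samples in mutated.items():
        n_mut = len(samples)
        if n_mut / n_samples <= min_mut_fraction:
            n_omitted += 1
            continue
        gi = row_pos[gene]
        cols = np.array([col_pos[s] for s in samples if s in col_pos])
        g = gof_mat[gi, cols]
        l_abs = np.abs(lof_mat[gi, cols])
        valid = np.isfinite(g) & np.isfinite(l_abs)
        gof_frac = float(np.sum(g[valid] > l_abs[valid])) / n_mut
        lof_frac = float(np.sum(l_abs[valid] > g[valid])) / n_mut
        if gof_frac > 0.5:
            status = "GoF"
        elif lof_frac > 0.5:
            status = "LoF"
        else:
            status = "unclassified"
        labels.append(GeneLabel(gene, status, gof_frac, lof_frac, n_mut))
    logger.info(
        "classified %d genes (%d omitted by the >%g mutation-frequency filter)",
        len(labels), n_omitted, min_mut_fraction,
    )
    return labels


def labels_to_frame(labels) -> pd.DataFrame:
    """Tabulate GeneLabel records (one row per gene)."""
    return pd.DataFrame(
        [(l.gene, l.status, l.gof_gene_score, l.lof_gene_score, l.n_mutated_samples) for l in labels],
        columns=LABEL_COLUMNS,
    )
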