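"""Aligned multi-omics containers: variant records and cohort matrices."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import InputError

__all__ = ["VariantRecord", "OmicsCohort", "GeneSampleActivity"]


@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant call for a (sample, gene) pair.

    ``mutation_class`` is a MAF-style variant classification already mapped
    onto the modeled category set (silent and unrecognized classes are mapped
    to ``No_Mutation`` upstream). ``recurrent`` is filled by the recurrence
    caller; the raw record carries ``False``.
    """

    sample_id: str
    gene: str
    mutation_class: str
    protein_position: Optional[int] = None
    genomic_position: Optional[tuple] = None  # (contig, coordinate)
    recurrent: bool = False

    def position_key(self):
        """Resolvable position used for recurrence grouping, or None.

        Prefers the amino-acid position, falling back to the genomic
        coordinate.
        """
        if self.protein_position is not None:
            return ("protein", int(self.protein_position))
        if self.genomic_position is not None:
            return ("genomic", tuple(self.genomic_position))
        return None


@dataclass
class OmicsCohort:
    """Matched mutation, expression and copy-number data over one cohort.

    Expression and copy-number are genes x samples DataFrames sharing
    identical index/columns; copy number is on log2 copy-ratio scale.
    Every variant must refer to a sample and gene present in the matrices.
    """

    expression: pd.DataFrame
    copy_number: pd.DataFrame
    variants: list = field(default_factory=list)

    def __post_init__(self):
        if not self.expression.index.equals(self.copy_number.index):
            raise InputError("expression and copy-number matrices have different gene index")
        if not self.expression.columns.equals(self.copy_number.columns):
            raise InputError("expression and copy-number matrices have different sample columns")
        if self.expression.index.has_duplicates:
            dupes = self.expression.index[self.expression.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate gene identifiers: {dupes[:5]}")
        if self.expression.columns.has_duplicates:
            raise InputError("duplicate sample identifiers")
        sample_set = set(self.expression.columns)
        gene_set = set(self.expression.index)
        for v in self.variants:
            if v.sample_id not in sample_set:
                raise InputError(f"variant sample {v.sample_id!r} not in cohort")
            if v.gene not in gene_set:
                raise InputError(f"variant gene {v.gene!r} not in cohort")

    @property
    def samples(self) -> list:
        return list(self.expression.columns)

    @property
    def genes(self) -> list:
        return list(self.expression.index)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]


@dataclass(frozen=True)
class GeneSampleActivity:
    """Per gene x sample activity pair: GoF in [0, 1], LoF in [-1, 0]."""

    gene: str
    sample: str
    gof: float
    lof: float

    def __post_init__(self):
        if not (0.0 <= self.gof <= 1.0):
            raise InputError(f"gof score {self.gof} outside [0, 1]")
        if not (-1.0 <= self.lof <= 0.0):
            raise InputError(f"lof score {self.lof} outside [-1, 0]")

    @property
    def net(self) -> float:
        """Convenience net score gof + lof in [-1, 1]."""
        return self.gof + self.lof
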