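"""Readers and writers for the tabular formats the pipeline consumes.

All matrices are genes-as-rows, samples-as-columns, tab-delimited UTF-8
text with a header row of sample identifiers and the gene identifier in the
first column; score matrices are written with six decimals. Mutations are
MAF-like TSV with the columns Tumor_Sample_Barcode, Hugo_Symbol,
Variant_Classification and Protein_Change (or Start_position); extra
columns are ignored. Filter counts (rows read, deduplicated, silent-mapped)
are logged for auditability.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import OmicsCohort, VariantRecord
from .errors import FormatError
from .memberships import MUTATION_CODES, NO_MUTATION

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_mutations",
    "write_mutations",
    "read_drug_response",
    "write_drug_response",
    "load_cohort",
    "write_cohort",
]

MAF_SAMPLE_COL = "Tumor_Sample_Barcode"
MAF_GENE_COL = "Hugo_Symbol"
MAF_CLASS_COL = "Variant_Classification"
MAF_PROTEIN_COL = "Protein_Change"
MAF_CHROM_COL = "Chromosome"
MAF_START_COL = "Start_position"

_PROTEIN_POS_RE = re.compile(r"p\.[A-Za-z*]*(\d+)|(\d+)")


def read_matrix(path) -> pd.DataFrame:
    """Read a genes x samples TSV matrix with strict validation."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse TSV matrix ({exc})") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene identifiers {dupes[:5]}")
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise FormatError(f"{path}: missing/ragged cells in rows {rows[:5]}")
    try:
        out = df.astype(float)
    except ValueError:
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(numeric.isna().to_numpy())
        r, c = bad[0]
        raise FormatError(
            f"{path}: non-numeric cell at gene {df.index[r]!r}, sample {df.columns[c]!r}: {df.iat[r, c]!r}"
        ) from None
    return out


def write_matrix(df: pd.DataFrame, path, decimals: int = 6) -> None:
    """Write a genes x samples matrix as TSV with fixed-point values."""
    df.to_csv(Path(path), sep="\t", float_format=f"%.{decimals}f", index_label="gene")


def parse_protein_position(change) -> int | None:
    """Extract the amino-acid position from a protein-change string."""
    if change is None or (isinstance(change, float) and np.isnan(change)):
        return None
    m = _PROTEIN_POS_RE.search(str(change))
    if not m:
        return None
    return int(m.group(1) or m.group(2))


def read_mutations(path) -> list:
    """Read a MAF-like TSV into deduplicated :class:`VariantRecord` rows.

    Silent and unrecognized variant classifications are mapped to
    ``No_Mutation``; repeated (sample, gene, class, position) rows are
    dropped. Requires the sample/gene/classification columns and at least
    one of Protein_Change / Start_position.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (MAF_SAMPLE_COL, MAF_GENE_COL, MAF_CLASS_COL):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    has_protein = MAF_PROTEIN_COL in df.columns
    has_genomic = MAF_START_COL in df.columns
    if not has_protein and not has_genomic:
        raise FormatError(f"{path}: need column {MAF_PROTEIN_COL!r} or {MAF_START_COL!r}")

    n_read = len(df)
    n_silent = 0
    records, seen = [], set()
    for row in df.itertuples(index=False):
        row = row._asdict()
        cls = row[MAF_CLASS_COL]
        if cls not in MUTATION_CODES:
            n_silent += 1
            cls = NO_MUTATION
        protein_pos = parse_protein_position(row.get(MAF_PROTEIN_COL)) if has_protein else None
        genomic_pos = None
        if has_genomic and row.get(MAF_START_COL) and not pd.isna(row.get(MAF_START_COL)):
            contig = row.get(MAF_CHROM_COL, "") or ""
            try:
                genomic_pos = (str(contig), int(float(row[MAF_START_COL])))
            except ValueError:
                genomic_pos = None
        rec = VariantRecord(
            sample_id=str(row[MAF_SAMPLE_COL]),
            gene=str(row[MAF_GENE_COL]),
            mutation_class=cls,
            protein_position=protein_pos,
            genomic_position=genomic_pos,
        )
        key = (rec.sample_id, rec.gene, rec.mutation_class, rec.protein_position, rec.genomic_position)
        if key in seen:
            continue
        seen.add(key)
        records.append(rec)
    logger.info(
        "%s: read %d rows -> %d records (%d duplicates dropped, %d silent/unrecognized mapped to %s)",
        path, n_read, len(records), n_read - len(records), n_silent, NO_MUTATION,
    )
    return records


def write_mutations(variants, path) -> None:
    """Write variant records as a MAF-like TSV (round-trip compatible)."""
    rows = []
    for v in variants:
        rows.append(
            {
                MAF_GENE_COL: v.gene,
                MAF_SAMPLE_COL: v.sample_id,
                MAF_CLASS_COL: v.mutation_class,
                MAF_PROTEIN_COL: f"p.X{v.protein_position}X" if v.protein_position is not None else "",
                MAF_CHROM_COL: v.genomic_position[0] if v.genomic_position else "",
                MAF_START_COL: v.genomic_position[1] if v.genomic_position else "",
            }
        )
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def read_drug_response(path) -> pd.DataFrame:
    """Read a long-format drug response TSV (sample, metric, value)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "metric", "value"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    return df[["sample", "metric", "value"]]


def write_drug_response(df: pd.DataFrame, path) -> None:
    df.to_csv(Path(path), sep="\t", index=False)


def load_cohort(mutations_path, expression_path, copy_number_path) -> OmicsCohort:
    """Assemble an aligned cohort from the three input files.

    Samples and genes are intersected across the two matrices (order taken
    from the expression matrix); variants referring to samples or genes
    outside the matrices are dropped with a logged count.
    """
    expr = read_matrix(expression_path)
    cn = read_matrix(copy_number_path)
    genes = [g for g in expr.index if g in set(cn.index)]
    samples = [s for s in expr.columns if s in set(cn.columns)]
    if not genes or not samples:
        raise FormatError("expression and copy-number matrices share no genes or no samples")
    if len(genes) < len(expr.index) or len(samples) < len(expr.columns):
        logger.info("aligned cohort to %d shared genes x %d shared samples", len(genes), len(samples))
    expr = expr.loc[genes, samples]
    cn = cn.loc[genes, samples]
    variants = read_mutations(mutations_path)
    gene_set, sample_set = set(genes), set(samples)
    kept = [v for v in variants if v.gene in gene_set and v.sample_id in sample_set]
    if len(kept) < len(variants):
        logger.info("dropped %d variants outside the aligned cohort", len(variants) - len(kept))
    return OmicsCohort(expr, cn, kept)


def write_cohort(sim_or_cohort, outdir) -> dict:
    """Write a cohort's three input files (plus truth/response if present).

    Accepts an :class:`OmicsCohort` or a ``SimulatedCohort``; returns the
    mapping of logical name -> written path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = getattr(sim_or_cohort, "cohort", sim_or_cohort)
    paths = {
        "expression": outdir / "expression.tsv",
        "copy_number": outdir / "copy_number.tsv",
        "mutations": outdir / "mutations.maf.tsv",
    }
    write_matrix(cohort.expression, paths["expression"])
    write_matrix(cohort.copy_number, paths["copy_number"])
    write_mutations(cohort.variants, paths["mutations"])
    truth = getattr(sim_or_cohort, "truth", None)
    if truth is not None:
        paths["truth"] = outdir / "truth.tsv"
        truth.to_csv(paths["truth"], sep="\t", index=False)
    response = getattr(sim_or_cohort, "response", None)
    if response is not None:
        paths["response"] = outdir / "drug_response.tsv"
        write_drug_response(response, paths["response"])
    return paths
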