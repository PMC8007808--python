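"""Readers and writers for the plain-text interchange formats.

Expression travels as TSV with genes in rows (first column the gene id)
unless the orientation flag says otherwise; traits as CSV/TSV with the
sample id in the first column; module truth as a two-column map; gene sets
as GMT (see :mod:`comodule.enrichment`).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import COVARIATE_NAMES, DEFAULT_TRAIT_GROUPS, ExpressionMatrix, TraitTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_traits",
    "write_traits",
    "read_truth_labels",
    "write_truth_labels",
]

FLOAT_FORMAT = "%.17g"  # lossless for float64 roundtrips


def read_expression(path: str | Path, orientation: str = "genes-rows") -> ExpressionMatrix:
    """Read an expression TSV into the internal samples x genes orientation.

    ``orientation`` is "genes-rows" (default; rows are genes, columns are
    samples) or "samples-rows".  Duplicate identifiers, non-numeric cells
    and ragged rows are errors that name the offending location.
    """
    if orientation not in ("genes-rows", "samples-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path.name}: duplicate row ids: {dupes[:5]}")
    if df.columns.has_duplicates:
        dupes = sorted(df.columns[df.columns.duplicated()].unique())
        raise ValueError(f"{path.name}: duplicate column ids: {dupes[:5]}")
    raw = df.where(df.notna(), "nan").to_numpy()
    try:
        # numpy's str->float64 conversion is correctly rounded (pandas'
        # to_numeric is not), which keeps write/read roundtrips bit-exact
        values = raw.astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path.name}: non-numeric cell: {exc}") from exc
    if orientation == "genes-rows":
        expr = ExpressionMatrix(values.T, list(df.columns), list(df.index))
    else:
        expr = ExpressionMatrix(values, list(df.index), list(df.columns))
    logger.info(
        "read expression %s (%s): %d samples x %d genes",
        path.name, orientation, expr.n_samples, expr.n_genes,
    )
    return expr


def write_expression(
    expr: ExpressionMatrix, path: str | Path, orientation: str = "genes-rows"
) -> None:
    """Write expression as TSV; default orientation puts genes in rows."""
    frame = expr.to_frame()
    if orientation == "genes-rows":
        frame = frame.T
        frame.index.name = "gene_id"
    elif orientation == "samples-rows":
        frame.index.name = "sample_id"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_traits(
    path: str | Path,
    trait_groups: dict[str, str] | None = None,
    sep: str | None = None,
) -> TraitTable:
    """Read a trait table (first column sample id).

    Columns in :data:`COVARIATE_NAMES` become covariates; every remaining
    column must be present in ``trait_groups`` (default: the standard
    10-trait layout) or an error names it.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    groups = dict(DEFAULT_TRAIT_GROUPS if trait_groups is None else trait_groups)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    cov_cols = [c for c in df.columns if c in COVARIATE_NAMES]
    trait_cols = [c for c in df.columns if c not in COVARIATE_NAMES]
    unmapped = [c for c in trait_cols if c not in groups]
    if unmapped:
        raise ValueError(f"{path.name}: trait column(s) not in group map: {unmapped}")
    table = TraitTable(
        df[trait_cols].astype(float),
        df[cov_cols].astype(float),
        {t: groups[t] for t in trait_cols},
    )
    logger.info(
        "read traits %s: %d samples, %d traits, %d covariates",
        path.name, len(table.sample_ids), len(trait_cols), len(cov_cols),
    )
    return table


def write_traits(table: TraitTable, path: str | Path, sep: str = ",") -> None:
    df = pd.concat([table.traits, table.covariates], axis=1)
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep, float_format=FLOAT_FORMAT)


def read_truth_labels(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene_id"].astype(str), df["module"].astype(int)))


def write_truth_labels(labels: dict[str, int], path: str | Path) -> None:
    pd.DataFrame({"gene_id": list(labels), "module": list(labels.values())}).to_csv(
        path, sep="\t", index=False
    )
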