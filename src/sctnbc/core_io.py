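"""File readers and writers for the pipeline's plain-text formats.

Supported formats:

* expression — dense TSV (ids in header row/column) or MatrixMarket triplet
  with companion ``<path>.rows`` / ``<path>.cols`` id files;
* gene positions and copy-number segments — BED-like TSV with a header
  (coordinates 1-based inclusive);
* gene sets — standard GMT, with ``X_UP`` / ``X_DN`` pairs folded into one
  directional signature;
* survival cohorts — TSV with ``sample``, ``time``, ``event`` columns followed
  by one column per gene.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .types import (
    SCTNBCError,
    ExpressionMatrix,
    GeneSignature,
    assign_order_index,
    validate_segments,
)

logger = logging.getLogger(__name__)

EXPRESSION_FORMATS = ("tsv_dense", "matrix_market_triplet")


def read_expression(
    path: str,
    format: str = "tsv_dense",
    unit: str = "raw_tpm",
    orientation: str = "cells_by_genes",
) -> ExpressionMatrix:
    """Read an expression matrix, normalizing orientation to cells x genes.

    ``orientation`` declares the layout of the *file*; ``genes_by_cells``
    inputs are transposed on load.
    """
    if format not in EXPRESSION_FORMATS:
        raise SCTNBCError(f"unknown expression format {format!r}")
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise SCTNBCError(f"unknown orientation {orientation!r}")
    if not os.path.exists(path):
        raise SCTNBCError(f"expression file not found: {path}")

    if format == "tsv_dense":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        _check_unique(header[1:], "column")  # before pandas mangles duplicates
        df = pd.read_csv(path, sep="\t", index_col=0)
        _check_unique(df.index, "row")
        values = df.to_numpy(dtype=float)
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]
    else:
        mat = mmread(path)
        row_ids = _read_id_file(path + ".rows")
        col_ids = _read_id_file(path + ".cols")
        values = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
        if values.shape != (len(row_ids), len(col_ids)):
            raise SCTNBCError(
                f"matrix shape {values.shape} does not match id files "
                f"({len(row_ids)} x {len(col_ids)})"
            )

    if orientation == "genes_by_cells":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return ExpressionMatrix(values, row_ids, col_ids, unit)


def _check_unique(ids, label: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise SCTNBCError(f"duplicate {label} id in expression file: {dup!r}")


def _read_id_file(path: str) -> list[str]:
    if not os.path.exists(path):
        raise SCTNBCError(f"MatrixMarket id file not found: {path}")
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    _check_unique(ids, os.path.basename(path))
    return ids


def write_expression(
    path: str,
    expr: ExpressionMatrix,
    format: str = "tsv_dense",
    orientation: str = "cells_by_genes",
) -> None:
    """Write ``expr`` in the chosen dialect (round-trips with read_expression)."""
    if format not in EXPRESSION_FORMATS:
        raise SCTNBCError(f"unknown expression format {format!r}")
    values = expr.values
    row_ids, col_ids = expr.cell_ids, expr.gene_ids
    if orientation == "genes_by_cells":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    if format == "tsv_dense":
        df = pd.DataFrame(values, index=row_ids, columns=col_ids)
        df.index.name = "id"
        df.to_csv(path, sep="\t", float_format="%.10g")
    else:
        mmwrite(path, coo_matrix(values))
        # mmwrite appends .mtx when missing; normalize to the requested path
        if not os.path.exists(path) and os.path.exists(path + ".mtx"):
            os.replace(path + ".mtx", path)
        for suffix, ids in ((".rows", row_ids), (".cols", col_ids)):
            with open(path + suffix, "w") as fh:
                fh.write("\n".join(ids) + "\n")


def read_gmt(path: str) -> list[GeneSignature]:
    """Parse a GMT file into signatures, pairing ``_UP``/``_DN`` entries.

    An ``X_DN`` line without a matching ``X_UP`` line is a hard error; an
    ``X_UP`` line without a ``_DN`` partner stays a plain undirected
    signature named ``X_UP``.
    """
    raw: dict[str, list[str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SCTNBCError(f"{path}:{lineno}: GMT line needs name, description, genes")
            name = parts[0]
            genes = [g for g in parts[2:] if g]
            if not genes:
                raise SCTNBCError(f"{path}:{lineno}: empty gene list for set {name!r}")
            if name in raw:
                raise SCTNBCError(f"{path}: duplicate set name {name!r}")
            raw[name] = genes
            order.append(name)

    signatures: list[GeneSignature] = []
    consumed: set[str] = set()
    for name in order:
        if name in consumed:
            continue
        if name.endswith("_UP"):
            base = name[:-3]
            dn = base + "_DN"
            if dn in raw:
                signatures.append(
                    GeneSignature(base, raw[name], raw[dn], directional=True)
                )
                consumed.update({name, dn})
                continue
        if name.endswith("_DN"):
            base = name[:-3]
            if base + "_UP" not in raw:
                raise SCTNBCError(f"{path}: {name!r} has no matching {base + '_UP'!r} entry")
            continue  # handled when its _UP partner is reached
        signatures.append(GeneSignature(name, raw[name], [], directional=False))
        consumed.add(name)
    return signatures


def write_gmt(path: str, signatures: list[GeneSignature]) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            if sig.directional:
                fh.write("\t".join([sig.name + "_UP", "na"] + sig.up_genes) + "\n")
                fh.write("\t".join([sig.name + "_DN", "na"] + sig.down_genes) + "\n")
            else:
                fh.write("\t".join([sig.name, "na"] + sig.up_genes) + "\n")


def read_gene_positions(path: str) -> pd.DataFrame:
    """Read a BED-like gene position table and attach ``order_index``.

    Expected columns (header required): ``gene_id``, ``chromosome``,
    ``start`` and optionally ``end``.  Coordinates are 1-based inclusive.
    """
    df = pd.read_csv(path, sep="\t")
    return assign_order_index(df)


def write_gene_positions(path: str, genes: pd.DataFrame) -> None:
    cols = [c for c in ("gene_id", "chromosome", "start", "end", "order_index") if c in genes]
    genes[cols].to_csv(path, sep="\t", index=False)


def read_segments(path: str) -> pd.DataFrame:
    """Read a WES copy-number segment table (chromosome, start, end, call, mean_copy)."""
    df = pd.read_csv(path, sep="\t")
    return validate_segments(df)


def write_segments(path: str, segments: pd.DataFrame) -> None:
    segments.to_csv(path, sep="\t", index=False)


def read_survival_cohort(path: str):
    """Read a survival cohort TSV: sample, time, event, then gene columns.

    Returns ``(cohort, bulk_expr)`` where ``cohort`` has the three survival
    columns and ``bulk_expr`` is an :class:`ExpressionMatrix` (samples as
    cells) or None when no gene columns are present.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise SCTNBCError(f"survival cohort missing column {col!r}")
    if (df["time"] < 0).any():
        raise SCTNBCError("negative survival time")
    if not set(df["event"].unique()) <= {0, 1}:
        raise SCTNBCError("event column must be 0/1")
    cohort = df[["sample", "time", "event"]].copy()
    gene_cols = [c for c in df.columns if c not in ("sample", "time", "event")]
    bulk = None
    if gene_cols:
        bulk = ExpressionMatrix(
            df[gene_cols].to_numpy(dtype=float),
            [str(s) for s in df["sample"]],
            gene_cols,
            "normalized_log",
        )
    return cohort, bulk


def write_survival_cohort(path: str, cohort: pd.DataFrame, bulk: ExpressionMatrix | None = None) -> None:
    out = cohort[["sample", "time", "event"]].copy()
    if bulk is not None:
        expr_df = bulk.to_dataframe().reset_index(drop=True)
        out = pd.concat([out.reset_index(drop=True), expr_df], axis=1)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
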