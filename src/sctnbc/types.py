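"""Core domain types shared across the pipeline.

Conventions
-----------
* Expression matrices are **cells x genes** everywhere internally.  Readers
  transpose files declared as gene x cell.
* Gene genomic coordinates are 1-based inclusive; only the derived
  ``order_index`` (chromosome-then-position rank) matters downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Recognised expression units.
UNITS = ("raw_tpm", "log2_tpm1", "counts", "normalized_log")

#: Cell types the typing step may assign.
CELL_TYPES = (
    "epithelial",
    "t_cell",
    "b_cell",
    "macrophage",
    "stroma",
    "endothelial",
    "unassigned",
)

#: Per-million scaling constant for TPM.
TPM_TOTAL = 1e6


class SCTNBCError(ValueError):
    """Base class for user-facing errors raised by this package."""


@dataclass
class ExpressionMatrix:
    """A cells x genes expression matrix with an explicit unit tag.

    Parameters
    ----------
    values : ndarray of shape (n_cells, n_genes)
    cell_ids, gene_ids : ordered unique identifiers
    unit : one of :data:`UNITS`
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    unit: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.unit not in UNITS:
            raise SCTNBCError(f"unknown expression unit {self.unit!r}; expected one of {UNITS}")
        if self.values.ndim != 2:
            raise SCTNBCError("expression values must be a 2-D matrix")
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids):
            raise SCTNBCError(
                f"row count {n_cells} does not match number of cell ids {len(self.cell_ids)}"
            )
        if n_genes != len(self.gene_ids):
            raise SCTNBCError(
                f"column count {n_genes} does not match number of gene ids {len(self.gene_ids)}"
            )
        for label, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise SCTNBCError(f"duplicate {label} id: {i!r}")
                seen.add(i)
        if not np.all(np.isfinite(self.values)):
            raise SCTNBCError("expression values must be finite")
        if self.unit in ("raw_tpm", "counts") and np.any(self.values < 0):
            c, g = np.argwhere(self.values < 0)[0]
            raise SCTNBCError(
                f"negative value under unit {self.unit!r} at cell "
                f"{self.cell_ids[c]!r}, gene {self.gene_ids[g]!r}"
            )

    # -- shape helpers -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def cell_index(self) -> pd.Index:
        return pd.Index(self.cell_ids, name="cell_id")

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids, name="gene_id")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_index(), columns=self.gene_index())

    # -- subsetting ----------------------------------------------------
    def subset_cells(self, keep: list[str] | np.ndarray) -> "ExpressionMatrix":
        """Return a matrix restricted to ``keep`` (ids or boolean/int mask)."""
        idx = _resolve_index(keep, self.cell_ids, "cell")
        return ExpressionMatrix(
            self.values[idx, :], [self.cell_ids[i] for i in idx], list(self.gene_ids), self.unit
        )

    def subset_genes(self, keep: list[str] | np.ndarray) -> "ExpressionMatrix":
        idx = _resolve_index(keep, self.gene_ids, "gene")
        return ExpressionMatrix(
            self.values[:, idx], list(self.cell_ids), [self.gene_ids[i] for i in idx], self.unit
        )

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, list(self.cell_ids), list(self.gene_ids), unit or self.unit)


def _resolve_index(keep, ids: list[str], label: str) -> np.ndarray:
    keep_arr = np.asarray(keep)
    if keep_arr.dtype == bool:
        if keep_arr.size != len(ids):
            raise SCTNBCError(f"boolean {label} mask has wrong length")
        return np.flatnonzero(keep_arr)
    if np.issubdtype(keep_arr.dtype, np.integer):
        return keep_arr
    lookup = {c: i for i, c in enumerate(ids)}
    missing = [k for k in keep_arr.tolist() if k not in lookup]
    if missing:
        raise SCTNBCError(f"unknown {label} ids: {missing[:5]}")
    return np.array([lookup[k] for k in keep_arr.tolist()], dtype=int)


@dataclass
class GeneSignature:
    """A named gene set; directional signatures carry a down list too."""

    name: str
    up_genes: list[str]
    down_genes: list[str] = field(default_factory=list)
    directional: bool = False

    def __post_init__(self) -> None:
        self.up_genes = _dedup(self.up_genes)
        self.down_genes = _dedup(self.down_genes)
        if not self.up_genes:
            raise SCTNBCError(f"signature {self.name!r} has an empty up-gene list")
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise SCTNBCError(
                f"signature {self.name!r}: genes in both up and down lists: {sorted(overlap)[:5]}"
            )


def _dedup(genes: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for g in genes:
        if g not in seen:
            seen.add(g)
            out.append(g)
    return out


# Column schemas for the tabular records (kept as pandas DataFrames).
CELL_RECORD_COLUMNS = [
    "cell_id",
    "patient_id",
    "sort_protocol",
    "library_size",
    "n_genes_expressed",
    "total_mrna",
    "size_factor",
    "cell_type",
    "cycling",
    "epithelial_cluster",
]

GENE_RECORD_COLUMNS = ["gene_id", "chromosome", "start", "order_index"]

SEGMENT_COLUMNS = ["chromosome", "start", "end", "call", "mean_copy"]


def validate_cell_records(cells: pd.DataFrame, n_genes: int | None = None) -> pd.DataFrame:
    """Validate a CellRecord table; returns the (possibly coerced) frame."""
    for col in ("cell_id", "patient_id"):
        if col not in cells.columns:
            raise SCTNBCError(f"cell record table missing column {col!r}")
    if cells["cell_id"].duplicated().any():
        dup = cells.loc[cells["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise SCTNBCError(f"duplicate cell id in records: {dup!r}")
    if "size_factor" in cells.columns and (cells["size_factor"].dropna() < 0).any():
        raise SCTNBCError("size factors must be non-negative")
    if n_genes is not None and "n_genes_expressed" in cells.columns:
        if (cells["n_genes_expressed"].dropna() > n_genes).any():
            raise SCTNBCError("n_genes_expressed exceeds total gene count")
    if "epithelial_cluster" in cells.columns and "cell_type" in cells.columns:
        bad = cells["epithelial_cluster"].notna() & (cells["cell_type"] != "epithelial")
        if bad.any():
            raise SCTNBCError("epithelial_cluster set on a non-epithelial cell")
    return cells


def chromosome_sort_key(chrom: str):
    """Natural ordering for chromosome names: 1..22 numerically, then X, Y, others."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.isdigit():
        return (0, int(c), "")
    return (1, 0, c)


def assign_order_index(genes: pd.DataFrame) -> pd.DataFrame:
    """Attach ``order_index`` (1..N) by chromosome-then-position sort.

    The input needs ``gene_id``, ``chromosome`` and ``start`` columns; ties in
    ``start`` are broken by gene id for determinism.
    """
    for col in ("gene_id", "chromosome", "start"):
        if col not in genes.columns:
            raise SCTNBCError(f"gene table missing column {col!r}")
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise SCTNBCError(f"duplicate gene id: {dup!r}")
    out = genes.copy()
    key = out["chromosome"].map(chromosome_sort_key)
    order = np.lexsort(
        (out["gene_id"].to_numpy(), out["start"].to_numpy(), key.to_numpy())
    )
    ranks = np.empty(len(out), dtype=int)
    ranks[order] = np.arange(1, len(out) + 1)
    out["order_index"] = ranks
    return out


def validate_segments(segments: pd.DataFrame) -> pd.DataFrame:
    for col in ("chromosome", "start", "end", "call"):
        if col not in segments.columns:
            raise SCTNBCError(f"segment table missing column {col!r}")
    if (segments["start"] >= segments["end"]).any():
        raise SCTNBCError("segment with start >= end")
    bad_calls = set(segments["call"]) - {"gain", "loss", "neutral"}
    if bad_calls:
        raise SCTNBCError(f"unknown segment calls: {sorted(bad_calls)}")
    for chrom, grp in segments.groupby("chromosome"):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise SCTNBCError(f"overlapping segments on chromosome {chrom}")
    return segments


def log2_tpm1(values: np.ndarray) -> np.ndarray:
    """log2(x + 1), the standard log transform of TPM."""
    return np.log2(values + 1.0)


def mad(x: np.ndarray) -> float:
    """Raw median absolute deviation, median(|x - median(x)|), no constant."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))))


__all__ = [
    "UNITS",
    "CELL_TYPES",
    "TPM_TOTAL",
    "SCTNBCError",
    "ExpressionMatrix",
    "GeneSignature",
    "CELL_RECORD_COLUMNS",
    "GENE_RECORD_COLUMNS",
    "SEGMENT_COLUMNS",
    "validate_cell_records",
    "assign_order_index",
    "validate_segments",
    "chromosome_sort_key",
    "log2_tpm1",
    "mad",
    "replace",
]
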