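"""Cell and gene quality filters and the normalization chain.

The chain mirrors the analysis contract: per-cell QC metrics with a
low-tail MAD filter, a per-patient prevalence gene filter, a simplified
mode-anchored conversion of TPM to relative counts, median-ratio (or pooled
deconvolution) size factors, and an SVD-based removal of unwanted variation
driven by control genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .types import SCTNBCError, ExpressionMatrix, log2_tpm1, mad

logger = logging.getLogger(__name__)

#: log2(TPM+1) threshold below which a gene counts as unexpressed in a cell.
EXPRESSION_THRESHOLD = 0.1

QC_METRICS = ("library_size", "n_genes_expressed", "total_mrna")


def compute_cell_qc_metrics(
    expr: ExpressionMatrix,
    endogenous_genes: list[str] | None = None,
    threshold: float = EXPRESSION_THRESHOLD,
) -> pd.DataFrame:
    """Per-cell library size, expressed-gene count and total endogenous mRNA.

    ``n_genes_expressed`` counts genes with ``log2(value+1) >= threshold``.
    Without an endogenous/control annotation, ``total_mrna`` degenerates to
    ``library_size`` (logged).
    """
    if expr.unit not in ("raw_tpm", "counts"):
        raise SCTNBCError(f"QC metrics need raw values, got unit {expr.unit!r}")
    if expr.n_cells == 0 or expr.n_genes == 0:
        raise SCTNBCError("empty expression matrix")
    values = expr.values
    library_size = values.sum(axis=1)
    n_expressed = (log2_tpm1(values) >= threshold).sum(axis=1)
    if endogenous_genes is None:
        logger.info("no endogenous-gene annotation: total_mrna degenerates to library_size")
        total_mrna = library_size.copy()
    else:
        mask = np.isin(np.asarray(expr.gene_ids), np.asarray(list(endogenous_genes)))
        if not mask.any():
            raise SCTNBCError("no endogenous genes present in the matrix")
        total_mrna = values[:, mask].sum(axis=1)
    return pd.DataFrame(
        {
            "cell_id": expr.cell_ids,
            "library_size": library_size,
            "n_genes_expressed": n_expressed.astype(int),
            "total_mrna": total_mrna,
        }
    )


@dataclass
class MadFilterResult:
    kept_cells: list[str]
    removed_cells: list[str]
    removed_per_metric: dict[str, int]
    thresholds: dict[str, float]


def filter_cells_by_mad(metrics: pd.DataFrame, k: float = 4.0) -> MadFilterResult:
    """Remove cells more than ``k`` MADs below the median on any QC metric.

    The rule operates on ``log2(metric + 1)`` with the raw MAD (no 1.4826
    consistency constant); a cell is removed when *any* metric falls strictly
    below ``median - k * MAD``.
    """
    if k <= 0:
        raise SCTNBCError("MAD multiplier k must be > 0")
    if len(metrics) < 3:
        raise SCTNBCError("need at least 3 cells for a stable median/MAD")
    removed = np.zeros(len(metrics), dtype=bool)
    removed_per_metric: dict[str, int] = {}
    thresholds: dict[str, float] = {}
    for m in QC_METRICS:
        logvals = log2_tpm1(metrics[m].to_numpy(dtype=float))
        med = float(np.median(logvals))
        cutoff = med - k * mad(logvals)
        fails = logvals < cutoff
        thresholds[m] = cutoff
        removed_per_metric[m] = int(fails.sum())
        removed |= fails
    cell_ids = metrics["cell_id"].astype(str)
    return MadFilterResult(
        kept_cells=cell_ids[~removed].tolist(),
        removed_cells=cell_ids[removed].tolist(),
        removed_per_metric=removed_per_metric,
        thresholds=thresholds,
    )


def filter_genes_by_prevalence(
    expr: ExpressionMatrix,
    patient_labels: pd.Series | dict,
    threshold: float = EXPRESSION_THRESHOLD,
    prevalence: float = 0.95,
) -> list[str]:
    """Keep genes expressed in at least one patient.

    For each patient, the "silent" set holds genes with ``log2(TPM+1) <
    threshold`` in at least ``prevalence`` of that patient's cells; the genes
    removed are the intersection of all patients' silent sets.
    """
    labels = pd.Series(patient_labels)
    labels.index = labels.index.astype(str)
    missing = [c for c in expr.cell_ids if c not in labels.index]
    if missing:
        raise SCTNBCError(f"cells without patient label: {missing[:5]}")
    labels = labels.loc[expr.cell_ids]
    logv = log2_tpm1(expr.values)
    silent_all = np.ones(expr.n_genes, dtype=bool)
    for patient, grp in labels.groupby(labels):
        idx = np.flatnonzero(labels.to_numpy() == patient)
        if idx.size == 0:
            raise SCTNBCError(f"patient {patient!r} has no cells")
        frac_silent = (logv[idx, :] < threshold).mean(axis=0)
        silent_all &= frac_silent >= prevalence
    kept = [g for g, s in zip(expr.gene_ids, silent_all) if not s]
    logger.info("gene prevalence filter: kept %d of %d genes", len(kept), expr.n_genes)
    return kept


def estimate_relative_counts(
    expr: ExpressionMatrix, mode: str = "mode_anchored", min_scale: float = 1e-6
) -> ExpressionMatrix:
    """Simplified transform of TPM to relative counts.

    ``mode_anchored``: per cell, the most common nonzero TPM value is mapped
    to a count of 1 (counts = round(TPM / mode)).  When every nonzero value
    is distinct, the mode is located with a Gaussian KDE on log2 values.
    ``passthrough`` returns the TPM values relabelled as counts.
    """
    if expr.unit != "raw_tpm":
        raise SCTNBCError(f"relative-count estimation expects raw_tpm, got {expr.unit!r}")
    if mode == "passthrough":
        return expr.with_values(expr.values.copy(), unit="counts")
    if mode != "mode_anchored":
        raise SCTNBCError(f"unknown count-estimation mode {mode!r}")
    counts = np.zeros_like(expr.values)
    for i in range(expr.n_cells):
        row = expr.values[i]
        nz = row[row > 0]
        if nz.size == 0:
            logger.warning("cell %s has no nonzero values; counts set to 0", expr.cell_ids[i])
            continue
        anchor = _nonzero_mode(nz)
        scale = max(1.0 / anchor, min_scale)
        counts[i] = np.round(row * scale)
    return expr.with_values(counts, unit="counts")


def _nonzero_mode(nz: np.ndarray) -> float:
    values, freq = np.unique(nz, return_counts=True)
    if freq.max() > 1:
        return float(values[np.argmax(freq)])  # ties -> smallest value (np.unique sorts)
    if values.size == 1:
        return float(values[0])
    logv = np.log2(values)
    if np.ptp(logv) < 1e-12:
        return float(values[0])
    try:
        dens = gaussian_kde(logv)(logv)
        return float(values[np.argmax(dens)])
    except np.linalg.LinAlgError:  # singular covariance: nearly constant values
        return float(np.median(values))


def compute_size_factors(
    counts: ExpressionMatrix,
    method: str = "median_ratio",
    min_shared_genes: int = 100,
    pool_sizes: tuple[int, ...] = (21, 41, 61),
) -> pd.Series:
    """Per-cell size factors, rescaled to mean 1 over nonzero factors.

    ``median_ratio``: factor = median over genes (nonzero in all cells) of
    the cell's count divided by the gene's geometric mean; falls back to
    library-size factors when fewer than ``min_shared_genes`` such genes
    exist.  ``deconvolution``: ring pools of cells are summed, pool factors
    estimated by median ratio against the average cell, and per-cell factors
    recovered by least squares.  All-zero cells always get factor 0.
    """
    if counts.unit != "counts":
        raise SCTNBCError(f"size factors expect counts, got {counts.unit!r}")
    values = counts.values
    n_cells = values.shape[0]
    if n_cells == 0:
        raise SCTNBCError("empty matrix")
    nonzero_cell = values.sum(axis=1) > 0

    if method == "library_size":
        factors = values.sum(axis=1).astype(float)
    elif method == "median_ratio":
        shared = (values > 0).all(axis=0)
        if shared.sum() < min_shared_genes:
            logger.info(
                "median-ratio: only %d genes nonzero in all cells (<%d); "
                "falling back to library-size factors",
                int(shared.sum()),
                min_shared_genes,
            )
            factors = values.sum(axis=1).astype(float)
        else:
            sub = values[:, shared]
            log_geo = np.mean(np.log(sub), axis=0)
            ratios = sub / np.exp(log_geo)[None, :]
            factors = np.median(ratios, axis=1)
    elif method == "deconvolution":
        factors = _deconvolution_factors(values, pool_sizes)
    else:
        raise SCTNBCError(f"unknown size-factor method {method!r}")

    factors = np.where(nonzero_cell, factors, 0.0)
    positive = factors > 0
    if positive.any():
        factors = factors / factors[positive].mean()
    return pd.Series(factors, index=pd.Index(counts.cell_ids, name="cell_id"), name="size_factor")


def _deconvolution_factors(values: np.ndarray, pool_sizes: tuple[int, ...]) -> np.ndarray:
    """Ring-pool least-squares deconvolution of per-cell factors."""
    n_cells = values.shape[0]
    order = np.argsort(values.sum(axis=1))  # ring ordered by library size
    reference = values.mean(axis=0)
    ref_pos = reference > 0
    rows, targets = [], []
    for size in pool_sizes:
        size = min(size, n_cells)
        for start in range(n_cells):
            members = order[(start + np.arange(size)) % n_cells]
            pool = values[members].sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = pool[ref_pos] / reference[ref_pos]
            theta = float(np.median(ratio))
            row = np.zeros(n_cells)
            row[members] = 1.0
            rows.append(row)
            targets.append(theta)
    # anchor overall scale: sum of factors matches sum of library-size ratios
    rows.append(np.ones(n_cells))
    targets.append(float(values.sum(axis=1).sum() / reference.sum()))
    A = np.vstack(rows)
    b = np.asarray(targets)
    theta, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.maximum(theta, 0.0)


def normalize_by_size_factors(counts: ExpressionMatrix, factors: pd.Series) -> ExpressionMatrix:
    """log2(count / factor + 1) for cells with positive factors.

    Cells with factor 0 must be removed beforehand (hard error otherwise).
    """
    f = factors.loc[counts.cell_ids].to_numpy(dtype=float)
    if (f <= 0).any():
        bad = [c for c, v in zip(counts.cell_ids, f) if v <= 0]
        raise SCTNBCError(f"cells with zero size factor must be removed first: {bad[:5]}")
    return counts.with_values(np.log2(counts.values / f[:, None] + 1.0), unit="normalized_log")


def least_variable_genes(expr: ExpressionMatrix, n: int = 500) -> list[str]:
    """Default control genes for RUV: the n least-variable genes."""
    variances = expr.values.var(axis=0)
    idx = np.argsort(variances, kind="stable")[: min(n, expr.n_genes)]
    return [expr.gene_ids[i] for i in sorted(idx)]


def remove_unwanted_variation(
    expr: ExpressionMatrix, control_genes: list[str], k: int = 1
) -> ExpressionMatrix:
    """Residualize each gene on the top-k factors of the control-gene submatrix.

    Factors are the first ``k`` left singular vectors of the column-centered
    cells x controls block; every gene is regressed on them (with intercept)
    and replaced by residuals plus its mean.  ``k = 0`` is the identity.
    """
    if expr.unit != "normalized_log":
        raise SCTNBCError(f"RUV expects normalized_log expression, got {expr.unit!r}")
    if k < 0:
        raise SCTNBCError("k must be >= 0")
    if k == 0:
        return expr.with_values(expr.values.copy())
    if k >= expr.n_cells:
        raise SCTNBCError(f"k={k} must be smaller than the number of cells ({expr.n_cells})")
    ctrl = [g for g in control_genes if g in set(expr.gene_ids)]
    if not ctrl:
        raise SCTNBCError("no control genes present in the matrix")
    sub = expr.subset_genes(ctrl).values
    sub = sub - sub.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(sub, full_matrices=False)
    factors = u[:, :k]
    centered = expr.values - expr.values.mean(axis=0, keepdims=True)
    fitted = factors @ (factors.T @ centered)
    corrected = expr.values - fitted
    return expr.with_values(corrected)
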