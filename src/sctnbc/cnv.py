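"""Expression-inferred copy-number profiles, carrier/subclone calls and
cell-cell concordance maps.

The inference follows the sliding-window recipe: scale expression to
log2(TPM+1)/10, subtract the mean profile of a normal reference, drop genes
whose mean scaled expression (pre-subtraction) falls below a floor, clip,
average over a gene-order window within each chromosome, and finally center
every gene across cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.metrics import silhouette_score

from .types import SCTNBCError, ExpressionMatrix, log2_tpm1

logger = logging.getLogger(__name__)

#: Expression scale used throughout CNV inference: log2(TPM + 1) / 10.
CNV_SCALE = 10.0


@dataclass
class CenteredExpression:
    """Reference-subtracted scaled expression on the shared gene panel.

    ``scaled_mean`` keeps the per-gene mean of the scaled *tumor* expression
    (before reference subtraction) — the quantity the downstream gene filter
    thresholds on.
    """

    values: np.ndarray  # cells x genes, reference-subtracted
    cell_ids: list[str]
    gene_ids: list[str]
    scaled_mean: np.ndarray  # per-gene mean of scaled tumor expression
    n_shared_genes: int


@dataclass
class CNVMatrix:
    """Smoothed inferred copy-number scores (cells x ordered genes).

    ``values`` are centered per gene across cells; ``smoothed`` keeps the
    pre-centering window averages (used for burden scoring, where centering
    would cancel the signal of a half-prevalent subclone).
    """

    values: np.ndarray
    smoothed: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    gene_order: pd.DataFrame  # gene_id, chromosome, order_index of retained genes
    window: int
    clip: float

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class SubcloneCall:
    """Per-cell CNV burden, carrier flag and subclone label (NA = none)."""

    calls: pd.DataFrame  # cell_id, burden, carrier, subclone
    burden_threshold: float
    n_subclones: int


def reference_normalize(
    expr: ExpressionMatrix, normal_ref: ExpressionMatrix
) -> CenteredExpression:
    """Scale both matrices to log2(TPM+1)/10 on the shared gene panel and
    subtract the reference's per-gene mean from every tumor cell."""
    for m, label in ((expr, "tumor"), (normal_ref, "reference")):
        if m.unit != "raw_tpm":
            raise SCTNBCError(f"{label} matrix must be raw_tpm, got {m.unit!r}")
    shared = [g for g in expr.gene_ids if g in set(normal_ref.gene_ids)]
    if not shared:
        raise SCTNBCError("tumor and reference share no genes")
    logger.info("reference_normalize: %d shared transcripts", len(shared))
    tum = log2_tpm1(expr.subset_genes(shared).values) / CNV_SCALE
    ref = log2_tpm1(normal_ref.subset_genes(shared).values) / CNV_SCALE
    centered = tum - ref.mean(axis=0, keepdims=True)
    return CenteredExpression(
        values=centered,
        cell_ids=list(expr.cell_ids),
        gene_ids=shared,
        scaled_mean=tum.mean(axis=0),
        n_shared_genes=len(shared),
    )


def infer_cnv_profiles(
    centered: CenteredExpression,
    gene_records: pd.DataFrame,
    window: int = 100,
    clip: float = 3.0,
    min_mean: float = 0.1,
) -> CNVMatrix:
    """Sliding-window CNV inference over genomically ordered genes.

    Steps, in order: (1) drop genes with mean scaled tumor expression below
    ``min_mean``; (2) order the survivors by ``order_index``; (3) clip the
    reference-subtracted values to ``[-clip, clip]``; (4) average within a
    ``window``-gene window centered at each gene, truncated at chromosome
    boundaries; (5) center each gene across cells.  Chromosomes with fewer
    than 3 retained genes are excluded.
    """
    if window < 1:
        raise SCTNBCError("window must be >= 1")
    if window % 2 == 0:
        window += 1
        logger.info("even window incremented to %d", window)
    recs = gene_records.set_index("gene_id")
    missing = [g for g in centered.gene_ids if g not in recs.index]
    if missing:
        raise SCTNBCError(f"genes without genomic position: {missing[:5]}")

    keep = centered.scaled_mean >= min_mean
    kept_genes = [g for g, k in zip(centered.gene_ids, keep) if k]
    logger.info("CNV gene filter: kept %d of %d genes", len(kept_genes), len(centered.gene_ids))
    if not kept_genes:
        raise SCTNBCError("no genes above the mean-expression floor")

    order_df = (
        recs.loc[kept_genes, ["chromosome", "order_index"]]
        .reset_index()
        .sort_values("order_index", kind="stable")
        .reset_index(drop=True)
    )
    chrom_sizes = order_df.groupby("chromosome", sort=False)["gene_id"].size()
    small = chrom_sizes[chrom_sizes < 3].index.tolist()
    if small:
        logger.info("excluding chromosomes with <3 genes: %s", small)
        order_df = order_df[~order_df["chromosome"].isin(small)].reset_index(drop=True)
    if order_df.empty:
        raise SCTNBCError("no chromosome with at least 3 genes after filtering")

    gene_pos = {g: i for i, g in enumerate(centered.gene_ids)}
    cols = [gene_pos[g] for g in order_df["gene_id"]]
    clipped = np.clip(centered.values[:, cols], -clip, clip)

    smoothed = np.empty_like(clipped)
    half = window // 2
    start_col = 0
    for _, grp in order_df.groupby("chromosome", sort=False):
        n = len(grp)
        block = clipped[:, start_col : start_col + n]
        csum = np.cumsum(block, axis=1)
        csum = np.concatenate([np.zeros((block.shape[0], 1)), csum], axis=1)
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half + 1, n)
        smoothed[:, start_col : start_col + n] = (csum[:, hi] - csum[:, lo]) / (hi - lo)
        start_col += n

    values = smoothed - smoothed.mean(axis=0, keepdims=True)
    return CNVMatrix(
        values=values,
        smoothed=smoothed,
        cell_ids=list(centered.cell_ids),
        gene_ids=order_df["gene_id"].tolist(),
        gene_order=order_df,
        window=window,
        clip=clip,
    )


def cnv_burden(cnv: CNVMatrix) -> np.ndarray:
    """Mean squared pre-centering CNV score per cell.

    Burden is computed on the reference-subtracted window averages *before*
    the final across-cell centering: centering would make a 50%-prevalent
    gain block contribute identically to carriers and non-carriers.
    """
    return (cnv.smoothed**2).mean(axis=1)


def call_cnv_subclones(
    cnv: CNVMatrix,
    reference_cnv: CNVMatrix,
    percentile: float = 95.0,
    max_subclones: int = 6,
    min_silhouette: float = 0.1,
) -> SubcloneCall:
    """Flag carrier cells by burden against a normal-cell null, then cluster
    carriers into subclones.

    Carrier threshold: the ``percentile`` of burdens from ``reference_cnv``
    (the same inference run on held-out normal cells).  Carriers are grouped
    by average-linkage hierarchical clustering on Pearson distance of their
    centered CNV profiles, cutting the tree at the k (2..max) with the best
    mean silhouette; one subclone when the best silhouette < ``min_silhouette``.
    """
    if reference_cnv.n_cells == 0:
        raise SCTNBCError("no reference cells for the burden null")
    burden = cnv_burden(cnv)
    ref_burden = cnv_burden(reference_cnv)
    threshold = float(np.percentile(ref_burden, percentile))
    carrier = burden > threshold

    subclone = np.full(len(burden), np.nan)
    n_subclones = 0
    n_carriers = int(carrier.sum())
    if n_carriers >= 2:
        profiles = cnv.values[carrier]
        labels = _cluster_profiles(profiles, max_subclones, min_silhouette)
        subclone[carrier] = labels
        n_subclones = int(labels.max())
    elif n_carriers == 1:
        subclone[carrier] = 1
        n_subclones = 1

    calls = pd.DataFrame(
        {
            "cell_id": cnv.cell_ids,
            "burden": burden,
            "carrier": carrier,
            "subclone": subclone,
        }
    )
    return SubcloneCall(calls=calls, burden_threshold=threshold, n_subclones=n_subclones)


def _cluster_profiles(profiles: np.ndarray, max_k: int, min_silhouette: float) -> np.ndarray:
    n = profiles.shape[0]
    if n < 3:
        return np.ones(n, dtype=int)
    corr = np.corrcoef(profiles)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    tree = linkage(squareform(dist, checks=False), method="average")
    best_k, best_score, best_labels = 1, -np.inf, np.ones(n, dtype=int)
    for k in range(2, min(max_k, n - 1) + 1):
        labels = fcluster(tree, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(dist, labels, metric="precomputed")
        if score > best_score:
            best_k, best_score, best_labels = k, score, labels
    if best_k == 1 or best_score < min_silhouette:
        return np.ones(n, dtype=int)
    # relabel 1..k by cluster size for determinism
    sizes = pd.Series(best_labels).value_counts()
    remap = {old: new + 1 for new, old in enumerate(sizes.index)}
    return np.array([remap[l] for l in best_labels], dtype=int)


@dataclass
class CorrelationMap:
    matrix: pd.DataFrame  # cells x cells Spearman correlations
    group_means: pd.Series  # per-group mean off-diagonal within-group correlation
    excluded_cells: list[str] = field(default_factory=list)


def correlation_map(
    values: np.ndarray | ExpressionMatrix,
    cell_ids: list[str] | None = None,
    group_labels: pd.Series | dict | None = None,
) -> CorrelationMap:
    """Full pairwise Spearman correlation over genes for every cell pair,
    plus per-group mean off-diagonal correlation.

    Constant cell profiles have undefined rank correlations; they are
    excluded and logged.
    """
    if isinstance(values, ExpressionMatrix):
        cell_ids = list(values.cell_ids)
        values = values.values
    if cell_ids is None:
        cell_ids = [str(i) for i in range(values.shape[0])]
    constant = np.ptp(values, axis=1) == 0
    excluded = [c for c, bad in zip(cell_ids, constant) if bad]
    if excluded:
        logger.info("excluding %d constant cell profiles from the correlation map", len(excluded))
    keep = ~constant
    kept_ids = [c for c, ok in zip(cell_ids, keep) if ok]
    if keep.sum() < 2:
        raise SCTNBCError("need at least 2 non-constant cells")
    ranks = np.apply_along_axis(rankdata, 1, values[keep])
    corr = np.corrcoef(ranks)
    mat = pd.DataFrame(corr, index=kept_ids, columns=kept_ids)

    group_means = pd.Series(dtype=float)
    if group_labels is not None:
        labels = pd.Series(group_labels)
        labels.index = labels.index.astype(str)
        means = {}
        for grp, members in labels.groupby(labels):
            ids = [c for c in members.index if c in mat.index]
            if len(ids) < 2:
                raise SCTNBCError(f"group {grp!r} has fewer than 2 usable cells")
            sub = mat.loc[ids, ids].to_numpy()
            off = sub[~np.eye(len(ids), dtype=bool)]
            means[grp] = float(off.mean())
        group_means = pd.Series(means, name="mean_within_correlation")
    return CorrelationMap(matrix=mat, group_means=group_means, excluded_cells=excluded)
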