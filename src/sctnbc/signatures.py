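"""Signature scoring, per-cell subtype assignment, cluster-signature
derivation and over-representation tests."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .types import SCTNBCError, ExpressionMatrix, GeneSignature
from .celltype import score_gene_set

logger = logging.getLogger(__name__)


def score_directional_signature(expr: ExpressionMatrix, signature: GeneSignature) -> pd.Series:
    """mean(up genes present) - mean(down genes present); with an empty down
    list this reduces to the plain gene-set mean."""
    up = score_gene_set(expr, signature.up_genes, name=f"{signature.name} (up)")
    if not signature.down_genes:
        return up.rename(signature.name)
    present_down = [g for g in signature.down_genes if g in set(expr.gene_ids)]
    if not present_down:
        logger.info("signature %r: no down gene present; score is mean(up)", signature.name)
        return up.rename(signature.name)
    down = score_gene_set(expr, present_down, name=f"{signature.name} (down)")
    return (up - down).rename(signature.name)


def score_signatures(expr: ExpressionMatrix, signatures: list[GeneSignature]) -> pd.DataFrame:
    """Cell x signature score matrix (directional where applicable)."""
    return pd.DataFrame({sig.name: score_directional_signature(expr, sig) for sig in signatures})


def assign_to_signature(scores: pd.DataFrame) -> pd.Series:
    """Per-cell argmax over signature scores; ties go to the first signature
    in name order (logged)."""
    if scores.shape[1] < 2:
        raise SCTNBCError("need at least 2 signatures to assign against")
    ordered = scores[sorted(scores.columns)]
    values = ordered.to_numpy()
    top = values.max(axis=1)
    ties = (values == top[:, None]).sum(axis=1) > 1
    if ties.any():
        logger.info("%d cells had tied top signature scores; first name wins", int(ties.sum()))
    idx = values.argmax(axis=1)  # argmax returns the first maximum
    return pd.Series(
        [ordered.columns[i] for i in idx], index=scores.index, name="signature"
    )


def derive_cluster_signature(
    expr: ExpressionMatrix,
    cluster_labels,
    target_cluster,
    n_top: int = 100,
    fdr: float = 0.05,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Top up-regulated genes of one cluster versus all other cells.

    Per gene: two-sided Wilcoxon rank-sum (target vs rest), Benjamini-
    Hochberg adjustment, keep adjusted p < ``fdr`` with positive log
    fold-change, rank by adjusted p then |lfc|, return the top ``n_top``.
    """
    labels = np.asarray(pd.Series(cluster_labels).to_numpy())
    if len(labels) != expr.n_cells:
        raise SCTNBCError("cluster labels must cover all cells")
    in_target = labels == target_cluster
    n_t = int(in_target.sum())
    if n_t == expr.n_cells:
        raise SCTNBCError("target cluster contains every cell; no comparison group")
    if n_t < min_cells:
        raise SCTNBCError(f"target cluster has {n_t} cells (< {min_cells})")
    target = expr.values[in_target]
    rest = expr.values[~in_target]
    stat, pvals = mannwhitneyu(target, rest, axis=0, alternative="two-sided")
    lfc = target.mean(axis=0) - rest.mean(axis=0)
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    table = pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "statistic": stat,
            "p_value": pvals,
            "p_adjusted": padj,
            "log_fold_change": lfc,
        }
    )
    hits = table[(table["p_adjusted"] < fdr) & (table["log_fold_change"] > 0)].copy()
    hits["abs_lfc"] = hits["log_fold_change"].abs()
    hits = hits.sort_values(
        ["p_adjusted", "abs_lfc", "gene_id"], ascending=[True, False, True], kind="stable"
    ).drop(columns="abs_lfc")
    return hits.head(n_top).reset_index(drop=True)


def overrepresentation_test(query_genes, target_set, universe):
    """Hypergeometric upper-tail enrichment of ``query`` in ``target``.

    Returns ``(overlap, fold_enrichment, p)``; fold is observed/expected
    overlap (inf when the expectation is 0 but the overlap is not).
    """
    universe = set(universe)
    if not universe:
        raise SCTNBCError("empty gene universe")
    query = set(query_genes)
    target = set(target_set)
    if not query <= universe or not target <= universe:
        raise SCTNBCError("query and target must be subsets of the universe")
    N, K, n = len(universe), len(target), len(query)
    overlap = len(query & target)
    expected = n * K / N
    fold = overlap / expected if expected > 0 else (np.inf if overlap else 0.0)
    p = float(hypergeom.sf(overlap - 1, N, K, n)) if n and K else 1.0
    return overlap, fold, p


def genes_in_segments(
    segments: pd.DataFrame, gene_records: pd.DataFrame, call: str = "gain"
) -> list[str]:
    """Genes whose start position lies inside a segment with the given call."""
    if call not in ("gain", "loss", "neutral"):
        raise SCTNBCError(f"unknown segment call {call!r}")
    seg = segments[segments["call"] == call]
    gene_chroms = set(gene_records["chromosome"])
    unknown = sorted(set(seg["chromosome"]) - gene_chroms)
    if unknown:
        logger.info("segments on chromosomes absent from the gene table skipped: %s", unknown)
    out: list[str] = []
    for chrom, seg_grp in seg.groupby("chromosome"):
        genes = gene_records[gene_records["chromosome"] == chrom]
        if genes.empty:
            continue
        starts = genes["start"].to_numpy()
        hit = np.zeros(len(genes), dtype=bool)
        for _, row in seg_grp.iterrows():
            hit |= (starts >= row["start"]) & (starts <= row["end"])
        out.extend(genes.loc[hit, "gene_id"].tolist())
    return sorted(out)
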