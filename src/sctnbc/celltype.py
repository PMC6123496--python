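"""Marker-based cell typing with cluster refinement, and cycling calls."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import SCTNBCError, ExpressionMatrix, GeneSignature, mad

logger = logging.getLogger(__name__)


def score_gene_set(expr: ExpressionMatrix, gene_set, name: str = "gene set") -> pd.Series:
    """Per-cell mean expression over the genes of ``gene_set`` present in the
    matrix (duplicates de-duplicated, missing genes dropped and logged)."""
    if isinstance(gene_set, GeneSignature):
        name = gene_set.name
        gene_set = gene_set.up_genes
    genes = list(dict.fromkeys(gene_set))
    present = [g for g in genes if g in set(expr.gene_ids)]
    if not present:
        raise SCTNBCError(f"no gene of set {name!r} present in the matrix")
    if len(present) < len(genes):
        logger.info("set %r: %d of %d genes absent", name, len(genes) - len(present), len(genes))
    scores = expr.subset_genes(present).values.mean(axis=1)
    return pd.Series(scores, index=pd.Index(expr.cell_ids, name="cell_id"), name=name)


def assign_cell_types(
    expr: ExpressionMatrix,
    marker_sets: dict[str, list],
    cluster_labels: pd.Series | np.ndarray | None = None,
    margin: float = 1.1,
    majority: float = 0.7,
) -> pd.Series:
    """Two-step typing: marker-score argmax, then cluster-majority override.

    Step 1 assigns each cell the type with the highest marker score, unless
    the top score is <= 0 or fails the ``margin`` ratio against the runner-up
    (then ``unassigned``).  Step 2: within each cluster whose provisionally
    assigned cells agree at >= ``majority``, unassigned and minority cells are
    relabelled to the majority type.
    """
    if len(marker_sets) < 2:
        raise SCTNBCError("need marker sets for at least 2 cell types")
    for t, genes in marker_sets.items():
        g = genes.up_genes if isinstance(genes, GeneSignature) else genes
        if not g:
            raise SCTNBCError(f"empty marker set for type {t!r}")

    types = sorted(marker_sets)
    score_mat = np.column_stack(
        [score_gene_set(expr, marker_sets[t], name=t).to_numpy() for t in types]
    )
    order = np.argsort(score_mat, axis=1)
    top_idx = order[:, -1]
    top = score_mat[np.arange(len(top_idx)), top_idx]
    second = score_mat[np.arange(len(top_idx)), order[:, -2]]
    provisional = np.array([types[i] for i in top_idx], dtype=object)
    ambiguous = (top <= 0) | (top < margin * second)
    provisional[ambiguous] = "unassigned"

    labels = pd.Series(provisional, index=pd.Index(expr.cell_ids, name="cell_id"), name="cell_type")
    if cluster_labels is None:
        return labels

    clusters = pd.Series(np.asarray(cluster_labels), index=labels.index)
    final = labels.copy()
    for _, members in clusters.groupby(clusters):
        cells = members.index
        assigned = labels.loc[cells]
        assigned = assigned[assigned != "unassigned"]
        if assigned.empty:
            continue
        counts = assigned.value_counts()
        if counts.iloc[0] / len(assigned) >= majority:
            final.loc[cells] = counts.index[0]
    return final


def classify_cycling(
    expr: ExpressionMatrix,
    g1s_genes: list,
    g2m_genes: list,
    k: float = 2.0,
) -> pd.DataFrame:
    """Call cells cycling-high when either phase score exceeds its data-derived
    threshold of median + k * MAD (raw MAD); returns scores and the call."""
    g1s = score_gene_set(expr, g1s_genes, name="g1s")
    g2m = score_gene_set(expr, g2m_genes, name="g2m")
    high = np.zeros(expr.n_cells, dtype=bool)
    thresholds = {}
    for name, scores in (("g1s", g1s), ("g2m", g2m)):
        vals = scores.to_numpy()
        spread = mad(vals)
        thr = float(np.median(vals)) + k * spread
        if spread == 0 and np.ptp(vals) == 0:
            logger.info("phase %s: all scores equal; everyone classified low", name)
        thresholds[name] = thr
        high |= vals > thr
    out = pd.DataFrame(
        {
            "cell_id": expr.cell_ids,
            "g1s_score": g1s.to_numpy(),
            "g2m_score": g2m.to_numpy(),
            "cycling": np.where(high, "high", "low"),
        }
    )
    out.attrs["thresholds"] = thresholds
    return out
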