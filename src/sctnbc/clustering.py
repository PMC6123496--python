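"""Patient-effect regression, low-dimensional embedding and density-peak
clustering of epithelial cells."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .types import SCTNBCError, ExpressionMatrix, mad

logger = logging.getLogger(__name__)


def regress_out_patient(
    expr: ExpressionMatrix | np.ndarray, patient_labels
) -> np.ndarray:
    """Residuals of a gene-wise least-squares fit on patient indicators.

    With an intercept and a full set of patient dummies the residuals equal
    the expression minus each patient's per-gene mean; a patient with a single
    cell therefore gets residual 0 (warned).
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else np.asarray(expr, float)
    labels = np.asarray(pd.Series(patient_labels).to_numpy())
    if len(labels) != values.shape[0]:
        raise SCTNBCError("patient labels must cover all cells")
    residuals = np.empty_like(values, dtype=float)
    for patient in pd.unique(labels):
        idx = np.flatnonzero(labels == patient)
        if idx.size == 1:
            logger.warning("patient %r has a single cell; its residuals are 0", patient)
        residuals[idx] = values[idx] - values[idx].mean(axis=0, keepdims=True)
    return residuals


def embed_cells(
    residuals: np.ndarray,
    dims: int = 2,
    seed: int = 0,
    n_pcs: int = 50,
    perplexity: float | None = None,
) -> np.ndarray:
    """Top principal components followed by a t-SNE embedding (deterministic
    given ``seed``)."""
    X = np.asarray(residuals, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise SCTNBCError("need at least 10 cells to embed")
    if dims >= n:
        raise SCTNBCError(f"dims={dims} must be below the cell count ({n})")
    n_comp = min(n_pcs, n - 1, X.shape[1])
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    if perplexity is None:
        perplexity = min(30.0, max(5.0, (n - 1) / 4.0))
    perplexity = min(perplexity, (n - 1) / 3.0)
    tsne = TSNE(
        n_components=dims,
        random_state=seed,
        init="pca",
        perplexity=perplexity,
    )
    return tsne.fit_transform(pcs)


def density_peak_cluster(
    coordinates: np.ndarray,
    dc: float | None = None,
    dc_percentile: float = 2.0,
    center_mad_mult: float = 6.0,
) -> np.ndarray:
    """Density-peak clustering with automatic center selection.

    Local density rho_i counts points within the cutoff distance ``dc``
    (default: the ``dc_percentile``-th percentile of pairwise distances);
    delta_i is the distance to the nearest point of higher density (ties
    broken lexicographically on coordinates so the result is independent of
    input order), and the global density peak takes the maximum distance.
    Centers are upper outliers of gamma = rho * delta: points whose
    log(gamma) exceeds ``median + center_mad_mult * MAD`` of the positive
    log(gamma) values (gamma spans orders of magnitude, so the raw scale
    over-selects); every other point inherits the label of its nearest point
    of higher density.  Labels are 1..K.
    """
    X = np.asarray(coordinates, dtype=float)
    if X.ndim != 2:
        raise SCTNBCError("coordinates must be 2-D (points x dims)")
    n = X.shape[0]
    if n < 10:
        raise SCTNBCError("need at least 10 points")
    dists = pdist(X)
    if np.all(dists == 0):
        return np.ones(n, dtype=int)
    if dc is None:
        dc = float(np.percentile(dists, dc_percentile))
        if dc <= 0:
            dc = float(dists[dists > 0].min())
    D = squareform(dists)

    rho = (D < dc).sum(axis=1) - 1  # exclude self

    # deterministic, order-independent processing order:
    # descending density, ties broken lexicographically by coordinates
    order = np.lexsort(tuple(X[:, d] for d in reversed(range(X.shape[1]))) + (-rho,))
    delta = np.empty(n)
    parent = np.full(n, -1, dtype=int)
    for pos, i in enumerate(order):
        if pos == 0:
            delta[i] = D[i].max()
            continue
        earlier = order[:pos]
        j = earlier[np.argmin(D[i, earlier])]
        delta[i] = D[i, j]
        parent[i] = j

    gamma = rho * delta
    # gamma spans orders of magnitude, so the upper-outlier rule operates on
    # log(gamma); zero-gamma points (isolated or zero-density) cannot be centers
    positive = gamma > 0
    if positive.any():
        log_gamma = np.log(gamma[positive])
        threshold = float(np.median(log_gamma)) + center_mad_mult * mad(log_gamma)
        centers = np.flatnonzero(positive & (np.log(np.where(positive, gamma, 1.0)) > threshold))
    else:
        centers = np.array([], dtype=int)
    if centers.size == 0:
        centers = np.array([order[0]])

    labels = np.zeros(n, dtype=int)
    center_rank = {int(c): r + 1 for r, c in enumerate(sorted(centers, key=lambda c: -gamma[c]))}
    for i in order:
        if i in center_rank:
            labels[i] = center_rank[i]
        else:
            labels[i] = labels[parent[i]]
    return labels
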