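"""Survival validation: signature scoring of bulk samples, quartile
stratification, Kaplan-Meier curves, the K-group log-rank test and
univariate Cox regression.

Cox partial likelihood is maximized by Newton iterations with Breslow tie
handling (Efron available behind a flag).  The headline validation pairs a
continuous-score Cox fit with a 4-group log-rank on score quartiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .types import SCTNBCError, ExpressionMatrix, GeneSignature
from .celltype import score_gene_set

logger = logging.getLogger(__name__)

COEF_CAP = 10.0


def score_bulk_samples(bulk: ExpressionMatrix, signature: GeneSignature) -> pd.Series:
    """Mean expression of the signature's (present) genes per bulk sample."""
    genes = signature.up_genes if not signature.directional else signature.up_genes
    return score_gene_set(bulk, genes, name=signature.name)


def stratify_by_quartiles(scores) -> pd.Series:
    """Quartile labels 1..4 using linear-interpolation percentile cut points;
    ties at a cut point fall to the lower group."""
    s = pd.Series(scores, dtype=float)
    if len(s) < 8:
        raise SCTNBCError("need at least 8 samples to form quartiles")
    vals = s.to_numpy()
    if np.ptp(vals) == 0:
        raise SCTNBCError("constant scores cannot be stratified")
    q25, q50, q75 = np.percentile(vals, [25, 50, 75])
    groups = np.select(
        [vals <= q25, vals <= q50, vals <= q75], [1, 2, 3], default=4
    )
    return pd.Series(groups, index=s.index, name="quartile")


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct event/censoring time with the at-risk
    count, number of events, and the survival probability just after that
    time.  Censored times reduce the risk set without a factor.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise SCTNBCError("empty survival input")
    if t.size != e.size:
        raise SCTNBCError("times and events must have equal length")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = []
    surv = 1.0
    n = t.size
    i = 0
    while i < n:
        ti = t[i]
        j = i
        d = 0
        while j < n and t[j] == ti:
            d += e[j]
            j += 1
        at_risk = n - i
        if d > 0:
            surv *= 1.0 - d / at_risk
        rows.append({"time": ti, "at_risk": at_risk, "events": d, "survival": surv})
        i = j
    return pd.DataFrame(rows)


def logrank_test(group_labels, times, events):
    """Unweighted K-group log-rank test.

    Returns ``(chi_square, df, p)`` with df = K - 1; the statistic uses the
    hypergeometric variance-covariance of the observed-minus-expected event
    counts at each distinct event time.
    """
    labels = np.asarray(pd.Series(group_labels).to_numpy())
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    groups = pd.unique(labels)
    K = len(groups)
    if K < 2:
        raise SCTNBCError("log-rank needs at least 2 groups")
    if e.sum() < 1:
        raise SCTNBCError("log-rank needs at least 1 event")
    group_idx = {g: i for i, g in enumerate(groups)}
    gi = np.array([group_idx[g] for g in labels])

    event_times = np.unique(t[e == 1])
    O = np.zeros(K)
    E = np.zeros(K)
    V = np.zeros((K, K))
    for ti in event_times:
        at_risk = t >= ti
        n_total = int(at_risk.sum())
        if n_total == 0:
            continue
        d_total = int(((t == ti) & (e == 1)).sum())
        n_g = np.bincount(gi[at_risk], minlength=K).astype(float)
        d_g = np.bincount(gi[(t == ti) & (e == 1)], minlength=K).astype(float)
        O += d_g
        E += d_total * n_g / n_total
        if n_total > 1:
            frac = n_g / n_total
            mult = d_total * (n_total - d_total) / (n_total - 1)
            V += mult * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[: K - 1]
    Vsub = V[: K - 1, : K - 1]
    stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    df = K - 1
    p = float(chi2.sf(stat, df))
    return stat, df, p


@dataclass
class CoxResult:
    coef: float
    hazard_ratio: float
    se: float
    p: float
    converged: bool
    separation: bool
    loglik: float


def _cox_quantities(beta: float, x, t, e, ties: str):
    """Breslow/Efron partial log-likelihood, score and information."""
    order = np.argsort(-t, kind="stable")  # decreasing time for running risk sums
    x, t, e = x[order], t[order], e[order]
    eta = beta * x
    w = np.exp(eta)
    loglik = score = info = 0.0
    s0 = s1 = s2 = 0.0
    i = 0
    n = len(t)
    while i < n:
        ti = t[i]
        j = i
        while j < n and t[j] == ti:
            s0 += w[j]
            s1 += w[j] * x[j]
            s2 += w[j] * x[j] ** 2
            j += 1
        deaths = [k for k in range(i, j) if e[k] == 1]
        d = len(deaths)
        if d:
            xsum = sum(x[k] for k in deaths)
            loglik += beta * xsum
            if ties == "breslow" or d == 1:
                loglik -= d * np.log(s0)
                score += xsum - d * s1 / s0
                info += d * (s2 / s0 - (s1 / s0) ** 2)
            else:  # efron
                wd = sum(w[k] for k in deaths)
                wdx = sum(w[k] * x[k] for k in deaths)
                wdx2 = sum(w[k] * x[k] ** 2 for k in deaths)
                for r in range(d):
                    f = r / d
                    a0 = s0 - f * wd
                    a1 = s1 - f * wdx
                    a2 = s2 - f * wdx2
                    loglik -= np.log(a0)
                    score += xsum / d - a1 / a0
                    info += a2 / a0 - (a1 / a0) ** 2
        i = j
    return loglik, score, info


def cox_univariate(
    score, times, events, ties: str = "breslow", tol: float = 1e-8, max_iter: int = 50
) -> CoxResult:
    """Univariate Cox proportional-hazards fit by Newton iterations.

    Monotone (separated) likelihoods are flagged and the coefficient capped
    at +/-10.
    """
    if ties not in ("breslow", "efron"):
        raise SCTNBCError(f"unknown tie handling {ties!r}")
    x = np.asarray(score, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.ptp(x) == 0:
        raise SCTNBCError("covariate does not vary")
    if e.sum() < 2:
        raise SCTNBCError("need at least 2 events")
    x = x - x.mean()  # centering stabilizes exp() without changing beta

    beta = 0.0
    converged = False
    separation = False
    loglik, sc, info = _cox_quantities(beta, x, t, e, ties)
    for _ in range(max_iter):
        if info <= 0:
            break
        step = sc / info
        new_beta = beta + step
        new_ll, new_sc, new_info = _cox_quantities(new_beta, x, t, e, ties)
        halvings = 0
        while new_ll < loglik - 1e-12 and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_sc, new_info = _cox_quantities(new_beta, x, t, e, ties)
            halvings += 1
        if abs(new_beta) > COEF_CAP:
            separation = True
            beta = float(np.clip(new_beta, -COEF_CAP, COEF_CAP))
            loglik, sc, info = _cox_quantities(beta, x, t, e, ties)
            logger.warning("monotone partial likelihood; coefficient capped at %g", beta)
            break
        delta = abs(new_beta - beta)
        beta, loglik, sc, info = new_beta, new_ll, new_sc, new_info
        if delta < tol:
            converged = True
            break
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    p = float(2.0 * norm.sf(abs(beta) / se)) if np.isfinite(se) else np.nan
    return CoxResult(
        coef=float(beta),
        hazard_ratio=float(np.exp(beta)),
        se=float(se),
        p=p,
        converged=converged,
        separation=separation,
        loglik=float(loglik),
    )


def cox_score_test(score, times, events, ties: str = "breslow") -> float:
    """Chi-square score statistic of the Cox model at beta = 0."""
    x = np.asarray(score, dtype=float)
    x = x - x.mean()
    _, sc, info = _cox_quantities(0.0, x, np.asarray(times, float), np.asarray(events, int), ties)
    if info <= 0:
        raise SCTNBCError("degenerate score test")
    return float(sc**2 / info)
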