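"""Analyses of the encoding matrix H: per-factor group tests, logistic
classifier AUC, k-means stratification with information gain, cluster/group
chi-square association, and per-feature ANOVA across clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as ss
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .containers import SampleSheet

log = logging.getLogger("nmfomics")

__all__ = [
    "FactorGroupTest",
    "ClusteringResult",
    "mann_whitney_per_factor",
    "logistic_auc",
    "kmeans_clusters",
    "information_gain",
    "cluster_group_chi2",
    "anova_across_clusters",
    "rank_auc",
]


@dataclass
class FactorGroupTest:
    factor: str
    U: float          # min-U convention
    p_value: float
    direction: int    # sign of (median_case - median_control)


@dataclass
class ClusteringResult:
    k: int
    assignments: pd.Series
    contingency: pd.DataFrame
    information_gain: float
    chi2: float
    chi2_p: float


# --------------------------------------------------------------------------- #
# group tests
# --------------------------------------------------------------------------- #
def mann_whitney_per_factor(H: pd.DataFrame, sheet: SampleSheet) -> list:
    """Two-sided Mann-Whitney U per factor (H row), case vs control.

    U is reported in the min-U convention (ties count 1/2 toward U).  Exact
    enumeration is used when both groups have <= 8 samples and no ties occur;
    otherwise the tie-corrected normal approximation.
    """
    sheet.require_two_per_group()
    case_ids, ctrl_ids = sheet.split()
    tests = []
    for factor in H.index:
        x = H.loc[factor, case_ids].to_numpy(dtype=float)
        y = H.loc[factor, ctrl_ids].to_numpy(dtype=float)
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "asymptotic"
        res = ss.mannwhitneyu(x, y, alternative="two-sided", method=method)
        u_case = float(res.statistic)
        u_min = min(u_case, len(x) * len(y) - u_case)
        direction = int(np.sign(np.median(x) - np.median(y)))
        tests.append(FactorGroupTest(factor=str(factor), U=u_min,
                                     p_value=float(res.pvalue), direction=direction))
    return tests


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank statistic: P(score_case > score_control), ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs both classes")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (len(pos) * len(neg)))


def logistic_auc(H: pd.DataFrame, sheet: SampleSheet, factor_subset=None):
    """Multivariate logistic regression of group on latent factors.

    Fitted by IRLS with a small ridge term (1e-6) so complete separation does
    not blow up the weights; Wald p per coefficient from the penalised
    information matrix; AUC is the in-sample rank statistic of the fitted
    scores.  Returns ``(coefficients DataFrame, auc)``.
    """
    sheet.require_two_per_group()
    factors = list(factor_subset) if factor_subset is not None else list(H.index)
    X = H.loc[factors, sheet.samples].to_numpy(dtype=float).T
    y = (sheet.group.to_numpy() == "case").astype(float)
    n, p = X.shape
    Xd = np.hstack([np.ones((n, 1)), X])
    ridge = 1e-6
    beta = np.zeros(p + 1)
    converged = False
    for _ in range(100):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        XtWX = Xd.T @ (w[:, None] * Xd) + ridge * np.eye(p + 1)
        grad = Xd.T @ (y - mu) - ridge * beta
        step = np.linalg.solve(XtWX, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            converged = True
            break
    if not converged:
        log.warning("logistic IRLS did not converge in 100 steps; returning last iterate")
    eta = Xd @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.clip(mu * (1 - mu), 1e-10, None)
    cov = np.linalg.inv(Xd.T @ (w[:, None] * Xd) + ridge * np.eye(p + 1))
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * ss.norm.sf(np.abs(z))
    coef = pd.DataFrame(
        {"coef": beta, "se": se, "z": z, "p": pvals},
        index=["intercept"] + [str(f) for f in factors],
    )
    auc = rank_auc(eta, y.astype(bool))
    return coef, auc


# --------------------------------------------------------------------------- #
# clustering
# --------------------------------------------------------------------------- #
def kmeans_clusters(X: pd.DataFrame, k: int, n_init: int = 10, seed: int = 0,
                    use_pca: bool = False, n_components: int = 5) -> pd.Series:
    """K-means over samples (columns of X); optional first-5-PC reduction.

    ``use_pca=True`` is the mode for raw omics matrices (thousands of
    features): samples are projected on the first ``n_components`` principal
    components first.  Returns a Series sample_id -> cluster label.
    """
    if k >= X.shape[1] + 1:
        raise ValueError("k must be <= number of samples")
    pts = X.to_numpy(dtype=float).T  # samples x features
    if use_pca:
        ncomp = min(n_components, pts.shape[0] - 1, pts.shape[1])
        pts = PCA(n_components=ncomp, random_state=seed).fit_transform(pts)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(pts)
    return pd.Series(km.labels_, index=X.columns, name="cluster")


def _entropy_bits(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def information_gain(assignments: pd.Series, sheet: SampleSheet) -> float:
    """Mutual information between cluster assignment and group label, in bits.

    gain = H(group) - sum_c (n_c / n) H(group | cluster c); this is the
    entropy-reduction reading of the E = -sum p log2 p formula, the standard
    quantity for ranking clusterings of the same samples.
    """
    groups = sheet.group.loc[assignments.index]
    tab = pd.crosstab(assignments, groups)
    n = tab.to_numpy().sum()
    h_group = _entropy_bits(tab.sum(axis=0).to_numpy())
    h_cond = sum(
        (row.sum() / n) * _entropy_bits(row.to_numpy()) for _, row in tab.iterrows()
    )
    return h_group - h_cond


def cluster_group_chi2(contingency: pd.DataFrame):
    """Pearson chi-square on a clusters x groups count table.

    Zero-margin rows are dropped with a warning; a warning is also logged
    when any expected count falls below 5.
    """
    tab = contingency.to_numpy(dtype=float)
    keep = tab.sum(axis=1) > 0
    if not keep.all():
        log.warning("dropping %d empty cluster row(s) from chi-square table",
                    (~keep).sum())
        tab = tab[keep]
    n = tab.sum()
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / n
    if (expected < 5).any():
        log.warning("chi-square expected count < 5; approximation is rough")
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = float(np.nansum((tab - expected) ** 2 / np.where(expected == 0, np.nan, expected)))
    df = (tab.shape[0] - 1) * (tab.shape[1] - 1)
    p = float(ss.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, p


def cluster_and_test(X: pd.DataFrame, sheet: SampleSheet, k: int, n_init: int = 10,
                     seed: int = 0, use_pca: bool = False) -> ClusteringResult:
    """Cluster samples, then score the clustering against the group labels."""
    assignments = kmeans_clusters(X, k, n_init=n_init, seed=seed, use_pca=use_pca)
    contingency = pd.crosstab(assignments, sheet.group.loc[assignments.index])
    gain = information_gain(assignments, sheet)
    chi2, p = cluster_group_chi2(contingency)
    return ClusteringResult(k=k, assignments=assignments, contingency=contingency,
                            information_gain=gain, chi2=chi2, chi2_p=p)


def anova_across_clusters(values: pd.Series, assignments: pd.Series):
    """One-way fixed-effects ANOVA of a feature across sample clusters.

    Clusters with fewer than 2 members are excluded with a warning.
    """
    groups = []
    for label in sorted(assignments.unique()):
        members = assignments.index[assignments == label]
        v = values.loc[members].to_numpy(dtype=float)
        if len(v) < 2:
            log.warning("cluster %s has < 2 members; excluded from ANOVA", label)
            continue
        groups.append(v)
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 clusters with >= 2 members")
    res = ss.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)
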