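"""Unsupervised discovery of cytokine-response immunotypes.

Individuals are clustered hierarchically (Ward linkage, Euclidean
distance) on inverse-rank-normalized cytokine responses; the number of
clusters is chosen by the average silhouette and supported by the gap
statistic (Monte Carlo reference datasets drawn uniformly over each
feature's observed range, normalized the same way as the data). Cluster
pairs are characterized with Mann-Whitney U tests for continuous
variables and chi-square tests for categorical ones, Bonferroni-adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .preprocess import inverse_rank_normalize

logger = logging.getLogger(__name__)


def _hierarchical_labels(X: np.ndarray, ks, method: str = "ward") -> dict:
    """Agglomerative labels for every k from a single linkage tree."""
    Z = linkage(X, method=method)
    return {k: fcluster(Z, t=k, criterion="maxclust") for k in ks}


def cluster_and_silhouette(X, k_range=range(2, 16), linkage_method: str = "ward"):
    """Labels per k plus the average-silhouette curve.

    Returns (labels dict k -> array, silhouette Series indexed by k).
    Degenerate data (all points identical) raises.
    """
    X = np.asarray(X, dtype=float)
    ks = list(k_range)
    if X.shape[0] <= max(ks):
        raise ValueError("need more points than the largest k")
    if np.allclose(X, X[0]):
        raise ValueError("all points identical; silhouette undefined")
    labels = _hierarchical_labels(X, ks, method=linkage_method)
    sil = {}
    for k in ks:
        lab = labels[k]
        if len(np.unique(lab)) < 2:
            sil[k] = np.nan
            continue
        sil[k] = float(silhouette_score(X, lab, metric="euclidean"))
    return labels, pd.Series(sil, name="silhouette")


def _within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """Pooled within-cluster dispersion W_k (Euclidean): sum over clusters
    of squared distances to the cluster centroid."""
    W = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        W += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return W


@dataclass
class GapCurve:
    k_values: list
    gap: pd.Series
    s_k: pd.Series
    log_w_data: pd.Series
    k_one_se: int  # smallest k with gap_k >= gap_{k+1} - s_{k+1}


def gap_statistic(X, k_range=range(1, 16), B: int = 100, seed: int = 0,
                  linkage_method: str = "ward", normalize=None) -> GapCurve:
    """Gap statistic for cluster-number selection.

    gap_k = mean_B[log W_k(reference)] - log W_k(data), with B reference
    datasets sampled uniformly over each feature's observed min-max range
    and passed through the same normalization as the data (``normalize``
    is a callable applied column-wise, e.g. inverse rank normalization;
    None for data already on its analysis scale). s_k is the reference
    log-dispersion standard deviation times sqrt(1 + 1/B). The reported
    one-standard-error choice is the smallest k with
    gap_k >= gap_{k+1} - s_{k+1}.
    """
    if B < 2:
        raise ValueError("need at least 2 reference datasets")
    X = np.asarray(X, dtype=float)
    if normalize is not None:
        X = np.column_stack([normalize(X[:, j]) for j in range(X.shape[1])])
    ks = list(k_range)
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)

    labels_data = _hierarchical_labels(X, [k for k in ks if k > 1],
                                       method=linkage_method)
    logW = {}
    for k in ks:
        lab = labels_data[k] if k > 1 else np.ones(X.shape[0], dtype=int)
        logW[k] = np.log(_within_dispersion(X, lab))

    ref_logW = np.empty((B, len(ks)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        if normalize is not None:
            ref = np.column_stack([normalize(ref[:, j])
                                   for j in range(ref.shape[1])])
        lab_ref = _hierarchical_labels(ref, [k for k in ks if k > 1],
                                       method=linkage_method)
        for ki, k in enumerate(ks):
            lab = lab_ref[k] if k > 1 else np.ones(X.shape[0], dtype=int)
            ref_logW[b, ki] = np.log(_within_dispersion(ref, lab))

    gap = pd.Series(ref_logW.mean(axis=0) - np.array([logW[k] for k in ks]),
                    index=ks)
    s_k = pd.Series(ref_logW.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B),
                    index=ks)

    k_one_se = ks[-1]
    for i, k in enumerate(ks[:-1]):
        if gap.iloc[i] >= gap.iloc[i + 1] - s_k.iloc[i + 1]:
            k_one_se = k
            break
    return GapCurve(k_values=ks, gap=gap, s_k=s_k,
                    log_w_data=pd.Series({k: logW[k] for k in ks}),
                    k_one_se=k_one_se)


@dataclass
class ClusterReport:
    labels: np.ndarray
    tests: pd.DataFrame  # variable, kind, statistic, p, p_bonferroni


def characterize_clusters(labels, covariate_table: pd.DataFrame,
                          categorical=None) -> ClusterReport:
    """Per-variable comparison tests between clusters.

    Two clusters: Mann-Whitney U (continuous) and chi-square without
    continuity correction (categorical); more clusters fall back to
    Kruskal-Wallis / omnibus chi-square with a logged note. Bonferroni
    adjustment across all tested variables. Clusters of size < 2 skip the
    tests with a warning.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if categorical is None:
        categorical = [c for c in covariate_table.columns
                       if covariate_table[c].dropna().nunique() <= 2]
    sizes = {u: int((labels == u).sum()) for u in uniq}
    if min(sizes.values()) < 2:
        logger.warning("characterize_clusters: cluster of size < 2; skipped")
        return ClusterReport(labels=labels, tests=pd.DataFrame(
            columns=["variable", "kind", "statistic", "p", "p_bonferroni"]))
    if len(uniq) > 2:
        logger.info("more than 2 clusters: using omnibus tests")

    rows = []
    for col in covariate_table.columns:
        x = covariate_table[col]
        groups = [x[labels == u].dropna().to_numpy() for u in uniq]
        if col in categorical:
            table = pd.crosstab(labels, x)
            if table.shape[1] < 2:
                stat, p = 0.0, 1.0
            else:
                stat, p, _, _ = stats.chi2_contingency(table, correction=False)
            kind = "chi2"
        else:
            if len(uniq) == 2:
                stat, p = stats.mannwhitneyu(groups[0], groups[1],
                                             alternative="two-sided")
                kind = "mannwhitney"
            else:
                stat, p = stats.kruskal(*groups)
                kind = "kruskal"
        rows.append({"variable": col, "kind": kind, "statistic": float(stat),
                     "p": float(p)})
    tests = pd.DataFrame(rows)
    m = len(tests)
    tests["p_bonferroni"] = np.minimum(tests["p"] * m, 1.0)
    return ClusterReport(labels=labels, tests=tests)


def immunotype_clusters(panel: pd.DataFrame, traits=None, k: int = None,
                        k_range=range(2, 16), B: int = 100, seed: int = 0):
    """End-to-end immunotype workflow on a cytokine panel.

    Selects the trait subset (default: all columns), inverse-rank
    normalizes complete cases, computes the silhouette curve and gap curve,
    and returns (labels at the chosen k, silhouette Series, GapCurve).
    ``k`` overrides the silhouette argmax.
    """
    sub = panel[traits] if traits is not None else panel
    sub = sub.dropna()
    X = np.column_stack([inverse_rank_normalize(sub[c].to_numpy())
                         for c in sub.columns])
    labels_by_k, sil = cluster_and_silhouette(X, k_range=k_range)
    gap = gap_statistic(X, k_range=range(1, max(k_range) + 1), B=B, seed=seed)
    chosen = int(k if k is not None else sil.idxmax())
    return pd.Series(labels_by_k[chosen], index=sub.index, name="cluster"), \
        sil, gap
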