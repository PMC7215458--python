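"""Spatial characteristics: feature screening, k-means clustering of
regions and statistical validation of the cluster solution.

Provinces are described by socio-economic indicators (population, GDP,
road freight volume, road-network length).  Indicators correlated with the
accident count above a threshold are candidate cluster features; among
them, the least mutually correlated pair is used so the two features carry
complementary information.  k is screened with the elbow (SSE vs k) curve
and the competing solutions are adjudicated by one-way ANOVA plus Tukey's
HSD on a per-region summary score: a solution whose clusters all differ
pairwise at the 0.05 level is preferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "FEATURE_COLUMNS",
    "ClusterValidation",
    "read_regions",
    "correlation_screen",
    "factor_scores",
    "elbow_sse",
    "kmeans_cluster",
    "validate_clusters",
]

FEATURE_COLUMNS = ("population", "gdp", "freight_volume", "road_length")


def read_regions(path) -> pd.DataFrame:
    """Read the region feature table (region, features..., accidents)."""
    frame = pd.read_csv(path)
    missing = [c for c in ("region", "accidents", *FEATURE_COLUMNS) if c not in frame.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    return frame


def _zscore(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def correlation_screen(
    features: pd.DataFrame, accident_counts: Sequence[float], threshold: float = 0.6
) -> dict:
    """Select the cluster-feature pair.

    Keeps features whose Pearson correlation with the accident counts
    exceeds ``threshold`` and, among the retained ones, picks the pair
    least correlated with each other (most complementary).  Returns the
    selected pair, the per-feature correlations and the feature-feature
    correlation matrix.
    """
    if features.shape[1] < 2:
        raise ValueError("need at least 2 candidate features")
    counts = np.asarray(accident_counts, dtype=float)
    with_counts = features.apply(lambda col: stats.pearsonr(col, counts)[0])
    kept = [c for c in features.columns if with_counts[c] > threshold]
    if not kept:
        raise ValueError(f"no feature correlates with accident counts above {threshold}")
    if len(kept) == 1:
        raise ValueError("only one feature passes the threshold; cannot form a pair")
    corr = features[kept].corr()
    best, best_r = None, np.inf
    for i, a in enumerate(kept):
        for b in kept[i + 1 :]:
            r = abs(corr.loc[a, b])
            if r < best_r:
                best, best_r = (a, b), r
    return {"selected": best, "with_counts": with_counts, "between": corr, "threshold": threshold}


def factor_scores(features: pd.DataFrame) -> np.ndarray:
    """Per-region comprehensive factor score.

    First principal component of the z-scored features, oriented so that
    larger feature values score higher.  This is the default scoring
    function behind cluster validation; any per-region score array can be
    passed to :func:`validate_clusters` instead.
    """
    Z = _zscore(features.to_numpy())
    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(Z)[:, 0]
    if pca.components_[0].sum() < 0:
        scores = -scores
    return scores


def elbow_sse(data: np.ndarray | pd.DataFrame, k_range: Sequence[int], seed: int = 0, n_restarts: int = 10) -> pd.DataFrame:
    """Within-cluster SSE for each k (best of ``n_restarts`` k-means runs).

    Also reports the discrete curvature of the SSE curve; the k values of
    maximal curvature are elbow candidates, advisory only — the final k
    should be adjudicated by :func:`validate_clusters`.
    """
    X = np.asarray(data, dtype=float)
    ks = sorted(k_range)
    if ks[0] < 1 or ks[-1] > len(X):
        raise ValueError("k_range must lie within [1, n]")
    sse = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
        sse.append(float(km.inertia_))
    out = pd.DataFrame({"k": ks, "sse": sse})
    curv = np.full(len(ks), np.nan)
    for i in range(1, len(ks) - 1):
        curv[i] = sse[i - 1] - 2 * sse[i] + sse[i + 1]
    out["curvature"] = curv
    out["elbow_candidate"] = False
    if len(ks) > 2:
        ranked = out["curvature"].rank(ascending=False)
        out.loc[ranked <= 2, "elbow_candidate"] = True
    return out


def kmeans_cluster(
    data: np.ndarray | pd.DataFrame, k: int, seed: int = 0, n_restarts: int = 10, standardize: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """k-means assignments and centroids, best of ``n_restarts`` by SSE.

    Features are z-scored by default: the cluster features (e.g. GDP and
    road length) live on incommensurate scales, and unstandardised
    Euclidean distance would let the larger-scale feature dominate.
    """
    X = np.asarray(data, dtype=float)
    if k > len(X):
        raise ValueError("k cannot exceed the number of observations")
    if standardize:
        X = _zscore(X)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
    return km.labels_.copy(), km.cluster_centers_.copy()


@dataclass
class ClusterValidation:
    """ANOVA + Tukey HSD validation of one cluster solution."""

    k: int
    assignments: np.ndarray
    cluster_means: pd.Series
    anova_p: float
    tukey: pd.DataFrame  # columns: cluster_a, cluster_b, p_value, significant
    verdict: bool
    excluded_singletons: list = field(default_factory=list)

    def offending_pairs(self) -> list[tuple]:
        return [
            (row.cluster_a, row.cluster_b)
            for row in self.tukey.itertuples()
            if not row.significant
        ]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "cluster_means": {str(k): float(v) for k, v in self.cluster_means.items()},
            "anova_p": float(self.anova_p),
            "tukey": self.tukey.assign(
                cluster_a=self.tukey.cluster_a.astype(str), cluster_b=self.tukey.cluster_b.astype(str)
            ).to_dict("records"),
            "verdict": bool(self.verdict),
            "excluded_singletons": [str(s) for s in self.excluded_singletons],
        }


def validate_clusters(assignments: Sequence, scores: Sequence[float], alpha: float = 0.05) -> ClusterValidation:
    """Test whether every pair of clusters differs in mean score.

    One-way ANOVA across clusters followed by Tukey's HSD on all pairs;
    the verdict is true iff the ANOVA rejects at ``alpha`` and every
    pairwise comparison does too (the pattern that distinguishes a clean
    k = 4 solution from a k = 5 one with two statistically
    indistinguishable clusters).  Singleton clusters cannot enter the
    comparisons and are excluded with a note.
    """
    labels = np.asarray(assignments)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("assignments and scores must have equal length")
    uniq, counts = np.unique(labels, return_counts=True)
    singles = [u for u, c in zip(uniq, counts) if c < 2]
    keep = ~np.isin(labels, singles)
    labels_k, scores_k = labels[keep], scores[keep]
    groups = [scores_k[labels_k == u] for u in np.unique(labels_k)]
    if len(groups) < 2:
        raise ValueError("need at least 2 clusters with >= 2 members")
    if np.ptp(scores_k) == 0:  # degenerate: identical scores everywhere
        uniq_all = np.unique(labels)
        tukey = pd.DataFrame(
            {
                "cluster_a": [a for i, a in enumerate(uniq_all) for a2 in uniq_all[i + 1 :]],
                "cluster_b": [a2 for i, a in enumerate(uniq_all) for a2 in uniq_all[i + 1 :]],
                "p_value": 1.0,
                "significant": False,
            }
        )
        means = pd.Series({u: float(scores[labels == u].mean()) for u in uniq})
        return ClusterValidation(
            k=len(uniq), assignments=labels, cluster_means=means, anova_p=1.0,
            tukey=tukey, verdict=False, excluded_singletons=singles,
        )
    anova_p = float(stats.f_oneway(*groups).pvalue)
    hsd = pairwise_tukeyhsd(scores_k, labels_k, alpha=alpha)
    frame = pd.DataFrame(hsd.summary().data[1:], columns=[str(c) for c in hsd.summary().data[0]])
    tukey = pd.DataFrame(
        {
            "cluster_a": frame["group1"],
            "cluster_b": frame["group2"],
            "p_value": frame["p-adj"].astype(float),
            "significant": frame["p-adj"].astype(float) <= alpha,
        }
    )
    means = pd.Series({u: float(scores[labels == u].mean()) for u in uniq})
    verdict = bool(anova_p <= alpha and tukey["significant"].all())
    return ClusterValidation(
        k=len(uniq),
        assignments=labels,
        cluster_means=means,
        anova_p=anova_p,
        tukey=tukey,
        verdict=verdict,
        excluded_singletons=singles,
    )
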