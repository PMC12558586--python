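"""Patient stratification: k-means on switch-feature matrices with
silhouette-based model selection, PCA projection, and per-cluster feature
enrichment tests.

k is chosen as the silhouette maximum over the candidate range (smaller k
wins ties); inertia is reported alongside for elbow inspection. Cluster
marker features are tested one-sided (cluster > rest) with a t test when
the feature passes Shapiro–Wilk normality at alpha 0.05 and a
Mann–Whitney U test otherwise, BH-corrected across all (cluster, feature)
pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, shapiro, ttest_ind
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .cohort import FeatureMatrix

log = logging.getLogger(__name__)

DEFAULT_SEED = 17
DEFAULT_N_INIT = 10
DEFAULT_NORMALITY_ALPHA = 0.05
DEFAULT_ENRICH_ADJP = 0.05
MIN_CLUSTER_SIZE_FOR_TEST = 3


@dataclass
class ClusterResult:
    k: int
    labels: pd.Series                 # patient id -> cluster
    silhouette: float
    inertia: float
    diagnostics: pd.DataFrame         # per candidate k: silhouette, inertia
    pca_coords: pd.DataFrame | None = None
    explained_variance: tuple[float, ...] = ()
    enriched_features: pd.DataFrame | None = None
    seed: int = DEFAULT_SEED


def select_k_and_cluster(
    matrix: FeatureMatrix,
    k_range: range | list[int] = range(2, 9),
    n_init: int = DEFAULT_N_INIT,
    seed: int = DEFAULT_SEED,
    min_cluster_frac: float = 0.05,
) -> ClusterResult:
    """Run k-means (k-means++ init) on the scaled matrix for every candidate
    k and keep the silhouette-maximizing solution (ties -> smaller k).

    Solutions containing a cluster smaller than ``max(2, min_cluster_frac *
    n)`` patients are inadmissible for selection (still reported in the
    diagnostics): on near-duplicate count profiles the raw silhouette
    otherwise degenerates toward isolating single noisy patients, and such
    micro-clusters carry no stratification value.
    """
    X = matrix.scaled.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 patients")
    if np.allclose(X, X[0]):
        raise ValueError("all patients identical after scaling; no cluster structure")
    n_distinct = len(np.unique(X, axis=0))
    size_floor = max(2, int(np.ceil(min_cluster_frac * n)))
    rows = []
    fits = {}
    for k in sorted(set(k_range)):
        # k beyond the number of distinct profiles cannot form k clusters
        if not 2 <= k <= min(n - 1, n_distinct):
            continue
        km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                    random_state=seed).fit(X)
        sil = float(silhouette_score(X, km.labels_, metric="euclidean"))
        min_size = int(np.bincount(km.labels_).min())
        rows.append((k, sil, float(km.inertia_), min_size,
                     min_size >= size_floor))
        fits[k] = km
    if not rows:
        raise ValueError("k_range contains no feasible k")
    diagnostics = pd.DataFrame(
        rows, columns=["k", "silhouette", "inertia", "min_cluster_size",
                       "admissible"])
    pool = diagnostics[diagnostics.admissible]
    if pool.empty:
        log.warning("every candidate k yields a cluster below %d patients; "
                    "selecting over all candidates", size_floor)
        pool = diagnostics
    best_k = int(pool.sort_values(["silhouette", "k"],
                                  ascending=[False, True]).iloc[0].k)
    km = fits[best_k]
    labels = pd.Series(km.labels_, index=matrix.scaled.index, name="cluster")
    best = diagnostics[diagnostics.k == best_k].iloc[0]
    return ClusterResult(
        k=best_k, labels=labels, silhouette=float(best.silhouette),
        inertia=float(best.inertia), diagnostics=diagnostics, seed=seed,
    )


def cluster_feature_tests(
    matrix: FeatureMatrix,
    labels: pd.Series,
    normality_alpha: float = DEFAULT_NORMALITY_ALPHA,
    adjp_max: float = DEFAULT_ENRICH_ADJP,
) -> pd.DataFrame:
    """One-sided (cluster > rest) marker tests per (cluster, feature).

    The test per feature is chosen by Shapiro–Wilk on the pooled values;
    constant features are skipped, as are clusters with fewer than 3
    members. Returns all tested rows with BH-adjusted p and an
    ``enriched`` flag (adj_p < ``adjp_max``).
    """
    counts = matrix.counts.loc[labels.index]
    clusters = sorted(labels.unique())
    rows = []
    for feature in counts.columns:
        values = counts[feature].to_numpy(dtype=float)
        if np.ptp(values) == 0:
            continue
        normal = shapiro(values).pvalue > normality_alpha
        for c in clusters:
            in_c = values[(labels == c).to_numpy()]
            rest = values[(labels != c).to_numpy()]
            if len(in_c) < MIN_CLUSTER_SIZE_FOR_TEST:
                log.warning("cluster %s has < %d members; tests skipped",
                            c, MIN_CLUSTER_SIZE_FOR_TEST)
                continue
            if normal:
                p = float(ttest_ind(in_c, rest, alternative="greater").pvalue)
                test = "t"
            else:
                p = float(mannwhitneyu(in_c, rest, alternative="greater").pvalue)
                test = "mannwhitney"
            rows.append((c, feature, test, p))
    if not rows:
        return pd.DataFrame(columns=["cluster", "feature", "test_used",
                                     "pvalue", "adj_p", "enriched"])
    df = pd.DataFrame(rows, columns=["cluster", "feature", "test_used", "pvalue"])
    df["adj_p"] = multipletests(df.pvalue, method="fdr_bh")[1]
    df["enriched"] = df.adj_p < adjp_max
    return df


def pca_project(matrix: FeatureMatrix) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Project the scaled matrix onto its top-2 principal components.

    Sign convention: each component's largest-magnitude loading is made
    positive, so repeated projections are identical. A rank-1 matrix gets a
    zero second coordinate with a warning.
    """
    X = matrix.scaled.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 non-constant columns for PCA")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    n_comp = min(2, max(rank, 1))
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(X)
    for i in range(n_comp):
        load = pca.components_[i]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, i] *= -1
    if n_comp < 2:
        log.warning("matrix has rank < 2; second PCA coordinate zeroed")
        coords = np.column_stack([coords, np.zeros(len(coords))])
        evr = (float(pca.explained_variance_ratio_[0]), 0.0)
    else:
        evr = tuple(float(v) for v in pca.explained_variance_ratio_[:2])
    frame = pd.DataFrame(coords, index=matrix.scaled.index, columns=["pc1", "pc2"])
    return frame, evr
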