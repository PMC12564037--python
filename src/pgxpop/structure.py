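"""Genotype-matrix PCA, K-means clustering and clustering-quality metrics.

Dosages are standardized per locus with Patterson scaling — mean-impute
missing entries, center by the column mean 2*p_hat, divide by
sqrt(p_hat*(1-p_hat)) — before a deterministic SVD.  Clustering and its
evaluation (silhouette, ARI, NMI) operate on the first two principal
components, matching the analysis space of the figures this pipeline
exports; scikit-learn provides the clustering and metric computations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_score,
)

from .cohort import MISSING, DosageMatrix


class StructureError(ValueError):
    pass


@dataclass
class ScaledMatrix:
    values: np.ndarray  # (n, L_kept) float
    rsids: list[str]
    means: np.ndarray  # 2 * p_hat per kept locus
    scales: np.ndarray  # sqrt(p_hat (1 - p_hat))
    dropped: list[str] = field(default_factory=list)


def scale_genotypes(dosages: DosageMatrix) -> ScaledMatrix:
    """Patterson-scale a dosage matrix; monomorphic loci are dropped."""
    d = dosages.values.astype(float)
    if d.shape[0] < 2:
        raise StructureError("need at least 2 samples")
    d[dosages.values == MISSING] = np.nan
    keep_cols, dropped = [], []
    means, scales = [], []
    cols = []
    for j, rsid in enumerate(dosages.rsids):
        col = d[:, j]
        called = col[~np.isnan(col)]
        if called.size == 0:
            dropped.append(rsid)
            continue
        p_hat = called.mean() / 2.0
        if p_hat <= 0.0 or p_hat >= 1.0:
            dropped.append(rsid)
            continue
        filled = np.where(np.isnan(col), called.mean(), col)
        cols.append((filled - 2.0 * p_hat) / np.sqrt(p_hat * (1.0 - p_hat)))
        keep_cols.append(rsid)
        means.append(2.0 * p_hat)
        scales.append(np.sqrt(p_hat * (1.0 - p_hat)))
    if not cols:
        raise StructureError("all loci monomorphic: nothing to scale")
    return ScaledMatrix(
        values=np.column_stack(cols),
        rsids=keep_cols,
        means=np.asarray(means),
        scales=np.asarray(scales),
        dropped=dropped,
    )


@dataclass
class PCAResult:
    scores: np.ndarray  # (n, k)
    loadings: np.ndarray  # (L, k)
    eigenvalues: np.ndarray  # non-increasing, variance scale
    rsids: list[str]
    dropped: list[str]


def pca(scaled: ScaledMatrix, n_components: int = 2) -> PCAResult:
    """Deterministic PCA of the scaled matrix via SVD.

    Sign convention: the largest-magnitude loading of each component is
    positive.  If the matrix rank is below ``n_components``, the available
    components are returned with a warning.
    """
    X = scaled.values
    n = X.shape[0]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    tol = S.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    rank = int((S > tol).sum())
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; "
            f"returning {k}"
        )
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # fix signs so repeated runs agree
    for c in range(k):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    scores = U * S
    eigenvalues = S**2 / (n - 1)
    return PCAResult(
        scores=scores,
        loadings=Vt.T,
        eigenvalues=eigenvalues,
        rsids=list(scaled.rsids),
        dropped=list(scaled.dropped),
    )


def kmeans(
    scores: np.ndarray, K: int, seed: int, n_init: int = 10
) -> np.ndarray:
    """K-means++ on the provided scores; best of ``n_init`` restarts."""
    scores = np.asarray(scores, float)
    if K < 1:
        raise StructureError("K must be >= 1")
    if K > scores.shape[0]:
        raise StructureError(f"K={K} exceeds the {scores.shape[0]} samples")
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed)
    return km.fit_predict(scores)


def silhouette(points: np.ndarray, labels) -> float:
    """Mean Euclidean silhouette; singleton clusters score 0 by convention."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise StructureError("silhouette undefined for a single cluster")
    return float(silhouette_score(np.asarray(points, float), labels))


def ari(labels_a, labels_b) -> float:
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise StructureError("label vectors must have equal length")
    return float(adjusted_rand_score(a, b))


def nmi(labels_a, labels_b, normalizer: str = "arithmetic") -> float:
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise StructureError("label vectors must have equal length")
    return float(normalized_mutual_info_score(a, b, average_method=normalizer))


@dataclass
class ClusterEval:
    K: int
    assignments: np.ndarray
    silhouette: float
    ari: float | None
    nmi: float | None
    composition: pd.DataFrame | None


def evaluate_clustering(
    scores: np.ndarray,
    K: int,
    seed: int,
    reference_labels=None,
    n_init: int = 10,
) -> ClusterEval:
    """Cluster PC scores at K and score the partition (optionally vs truth)."""
    assign = kmeans(scores, K, seed=seed, n_init=n_init)
    sil = silhouette(scores, assign) if K > 1 else float("nan")
    a = n = comp = None
    if reference_labels is not None:
        a = ari(assign, reference_labels)
        n = nmi(assign, reference_labels)
        comp = pd.crosstab(
            pd.Series(reference_labels, name="population"),
            pd.Series(assign, name="cluster"),
        )
    return ClusterEval(
        K=K, assignments=assign, silhouette=sil, ari=a, nmi=n, composition=comp
    )
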