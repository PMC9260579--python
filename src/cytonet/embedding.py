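"""Sample-level embeddings and multivariate group statistics.

Frequency matrices (one row per sample) are embedded with t-SNE for
visual QC - internal-control replicates should form the tightest group
- or with PCA, whose group centroids and scores feed Hotelling's
two-sample T² comparison of patient groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_samples


@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame        # samples x 2 (t-SNE) or x d (PCA)
    method: str
    seed: int | None = None
    perplexity: float | None = None
    explained_variance_ratio: np.ndarray | None = None
    centroids: pd.DataFrame | None = None
    replicate_silhouette: float | None = None
    components: np.ndarray | None = None
    mean_: np.ndarray | None = field(default=None, repr=False)


def embed_samples_tsne(
    prep_freq: pd.DataFrame,
    seed: int = 0,
    perplexity: float = 15.0,
) -> EmbeddingResult:
    """2-D t-SNE of samples; coordinates are centered, seed-reproducible."""
    x = np.asarray(prep_freq, dtype=float)
    n = x.shape[0]
    if n < 5:
        raise ValueError("too few samples for a t-SNE embedding")
    if perplexity >= (n - 1) / 3:
        raise ValueError("perplexity must be < (n_samples - 1) / 3")
    coords = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed,
        init="pca", method="barnes_hut",
    ).fit_transform(x)
    coords = coords - coords.mean(axis=0)
    index = prep_freq.index if isinstance(prep_freq, pd.DataFrame) else None
    return EmbeddingResult(
        coordinates=pd.DataFrame(coords, index=index, columns=["tsne1", "tsne2"]),
        method="tsne", seed=seed, perplexity=perplexity,
    )


def replicate_qc(coords: pd.DataFrame, replicate_mask: np.ndarray) -> float:
    """Mean silhouette of the replicate samples vs everything else.

    Treats replicates as one cluster and all other samples as a second;
    values near 1 mean the replicates are tightly co-located, near 0
    that they scatter among the rest.
    """
    mask = np.asarray(replicate_mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("need at least 2 replicate samples")
    if mask.all():
        raise ValueError("all samples are replicates; nothing to compare")
    x = np.asarray(coords, dtype=float)
    sil = silhouette_samples(x, mask.astype(int))
    return float(sil[mask].mean())


def pca_samples(
    prep_freq: pd.DataFrame,
    groups: pd.Series | None = None,
    n_components: int | None = None,
) -> EmbeddingResult:
    """PCA of the column-centered sample matrix with group centroids."""
    x = np.asarray(prep_freq, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if np.allclose(x, x.mean(axis=0)):
        raise ValueError("degenerate (rank-0) matrix")
    n_comp = n_components or min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(x)
    index = prep_freq.index if isinstance(prep_freq, pd.DataFrame) else None
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    coords = pd.DataFrame(scores, index=index, columns=cols)
    centroids = None
    if groups is not None:
        g = pd.Series(np.asarray(groups), index=coords.index)
        centroids = coords.groupby(g).mean()
    return EmbeddingResult(
        coordinates=coords, method="pca",
        explained_variance_ratio=pca.explained_variance_ratio_,
        centroids=centroids, components=pca.components_, mean_=pca.mean_,
    )


@dataclass
class T2Result:
    t2: float
    f: float
    df1: int
    df2: int
    p: float
    d: int


def hotelling_t2(group_a: np.ndarray, group_b: np.ndarray) -> T2Result:
    """Hotelling's two-sample T² with the F reference distribution.

    T² = (nA nB / (nA + nB)) (x̄A - x̄B)' S⁻¹ (x̄A - x̄B) with the pooled
    covariance S; F = ((nA + nB - d - 1) / (d (nA + nB - 2))) T² on
    (d, nA + nB - d - 1) degrees of freedom.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("groups must be 2-D with matching dimensionality")
    na, nb, d = a.shape[0], b.shape[0], a.shape[1]
    if na + nb - 2 <= d:
        raise ValueError("need nA + nB - 2 > d; reduce dimensionality first")
    diff = a.mean(axis=0) - b.mean(axis=0)
    sa = np.cov(a, rowvar=False, ddof=1).reshape(d, d)
    sb = np.cov(b, rowvar=False, ddof=1).reshape(d, d)
    pooled = ((na - 1) * sa + (nb - 1) * sb) / (na + nb - 2)
    try:
        sol = np.linalg.solve(pooled, diff)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular pooled covariance; reduce dimensions (e.g. PCA first)"
        ) from exc
    t2 = float(na * nb / (na + nb) * diff @ sol)
    df1, df2 = d, na + nb - d - 1
    f = t2 * df2 / (d * (na + nb - 2))
    p = float(stats.f.sf(f, df1, df2))
    return T2Result(t2=t2, f=float(f), df1=df1, df2=df2, p=p, d=d)


def hotelling_on_pca(
    prep_freq: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    d: int = 2,
) -> T2Result:
    """T² between two groups in the pooled-sample PCA score space."""
    emb = pca_samples(prep_freq, groups=groups, n_components=d)
    g = pd.Series(np.asarray(groups), index=emb.coordinates.index)
    return hotelling_t2(
        emb.coordinates[g == group_a].to_numpy(),
        emb.coordinates[g == group_b].to_numpy(),
    )
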