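"""Consensus-clustering subtype discovery with PCA validation and
between-subtype top-gene tables.

Each repetition subsamples a fraction of samples (and optionally features),
clusters them hierarchically (euclidean, average linkage) at every k, and
accumulates how often each sample pair co-clusters among the repetitions in
which both were drawn.  Final labels come from hierarchical clustering of
``1 - consensus``; k is selected by the relative delta-area of the consensus
CDF unless fixed by the caller.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from . import de as de_mod
from .io import ExpressionBundle, PipelineError

logger = logging.getLogger(__name__)


@dataclass
class ConsensusResult:
    consensus: dict[int, pd.DataFrame]       # k -> sample x sample matrix
    cdf: dict[int, np.ndarray]               # k -> CDF over the value grid
    cdf_grid: np.ndarray
    area: dict[int, float]                   # k -> area under the CDF
    delta_area: dict[int, float]             # k -> relative delta area
    selected_k: int
    labels: pd.Series = field(default=None)  # final labels at selected_k
    labels_by_k: dict[int, pd.Series] = field(default_factory=dict)


def _cluster_samples(sub: np.ndarray, k: int, method: str) -> np.ndarray:
    if method == "kmeans":
        from sklearn.cluster import KMeans

        return KMeans(n_clusters=k, n_init=10, random_state=0).fit_predict(sub.T)
    d = pdist(sub.T, metric="euclidean")
    return fcluster(linkage(d, method="average"), t=k, criterion="maxclust")


def consensus_cluster(
    matrix: pd.DataFrame,
    k_range=(2, 3, 4, 5),
    reps: int = 1000,
    p_item: float = 0.8,
    p_feature: float = 1.0,
    seed: int = 0,
    inner: str = "hierarchical",
    fixed_k: int | None = None,
) -> ConsensusResult:
    """Consensus clustering of samples (columns) of a feature matrix.

    ``fixed_k`` overrides the delta-area selection (consensus matrices for
    every k in ``k_range`` are still produced).
    """
    k_range = sorted(set(int(k) for k in k_range))
    if min(k_range) < 2:
        raise PipelineError("k_range minimum must be >= 2")
    n = matrix.shape[1]
    if max(k_range) > n:
        raise PipelineError("k exceeds the number of samples")
    if fixed_k is not None and fixed_k not in k_range:
        raise PipelineError(f"fixed_k={fixed_k} not in k_range {k_range}")
    rng = np.random.default_rng(seed)
    x = matrix.to_numpy(dtype=float)
    m = matrix.shape[0]
    n_items = max(2, math.ceil(p_item * n))
    n_feats = max(1, math.ceil(p_feature * m))

    together = {k: np.zeros((n, n)) for k in k_range}
    cosampled = np.zeros((n, n))
    for _ in range(reps):
        cols = np.sort(rng.choice(n, size=n_items, replace=False))
        rows = (
            np.arange(m)
            if n_feats == m
            else np.sort(rng.choice(m, size=n_feats, replace=False))
        )
        cosampled[np.ix_(cols, cols)] += 1.0
        sub = x[np.ix_(rows, cols)]
        for k in k_range:
            kk = min(k, len(cols))
            assign = _cluster_samples(sub, kk, inner)
            same = assign[:, None] == assign[None, :]
            together[k][np.ix_(cols, cols)] += same

    never = cosampled == 0
    if never.any() and n > 1:
        off_diag = never & ~np.eye(n, dtype=bool)
        if off_diag.any():
            logger.warning(
                "%d sample pairs never co-subsampled; consensus set to 0",
                int(off_diag.sum()) // 2,
            )
    consensus: dict[int, pd.DataFrame] = {}
    for k in k_range:
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(cosampled > 0, together[k] / np.where(cosampled > 0, cosampled, 1.0), 0.0)
        np.fill_diagonal(c, 1.0)
        c = (c + c.T) / 2.0
        consensus[k] = pd.DataFrame(c, index=matrix.columns, columns=matrix.columns)

    grid = np.linspace(0.0, 1.0, 101)
    cdf: dict[int, np.ndarray] = {}
    area: dict[int, float] = {}
    iu = np.triu_indices(n, k=1)
    for k in k_range:
        values = consensus[k].to_numpy()[iu]
        cdf[k] = np.array([(values <= g).mean() for g in grid])
        area[k] = float(np.trapezoid(cdf[k], grid))

    delta_area: dict[int, float] = {}
    for i, k in enumerate(k_range):
        if i == 0:
            delta_area[k] = area[k]
        else:
            prev = area[k_range[i - 1]]
            delta_area[k] = (area[k] - prev) / prev if prev > 0 else 0.0
    selected = fixed_k if fixed_k is not None else max(k_range, key=lambda k: (delta_area[k], -k))

    labels_by_k: dict[int, pd.Series] = {}
    for k in k_range:
        dist = squareform(1.0 - consensus[k].to_numpy(), checks=False)
        assign = fcluster(linkage(dist, method="average"), t=k, criterion="maxclust")
        labels_by_k[k] = pd.Series(assign, index=matrix.columns, name="subtype")
    return ConsensusResult(
        consensus=consensus,
        cdf=cdf,
        cdf_grid=grid,
        area=area,
        delta_area=delta_area,
        selected_k=selected,
        labels=labels_by_k[selected],
        labels_by_k=labels_by_k,
    )


def pca_embed(matrix: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample coordinates from column-centered SVD of the feature matrix.

    Returns (scores DataFrame with PC columns, explained variance ratios).
    """
    if matrix.shape[1] < 3:
        raise PipelineError("PCA needs >= 3 samples")
    x = matrix.to_numpy(dtype=float).T  # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    if np.allclose(x, 0):
        raise PipelineError("constant matrix: PCA undefined")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    var = s ** 2 / (x.shape[0] - 1)
    ratio = var / var.sum()
    n_components = min(n_components, scores.shape[1])
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores[:, :n_components], index=matrix.columns, columns=cols),
        ratio[:n_components],
    )


def subtype_de(
    bundle: ExpressionBundle,
    labels: pd.Series,
    top_n: int = 50,
    alpha: float = 0.05,
) -> dict:
    """Between-subtype differential expression (subtype 1 vs 2).

    Returns the top-``top_n`` mRNA and lncRNA tables by p-value together
    with z-scored expression sub-matrices for heatmap export.
    """
    labels = pd.Series(labels)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise PipelineError(f"need exactly 2 subtype labels, got {uniq}")
    for lab in uniq:
        if (labels == lab).sum() < 2:
            raise PipelineError(f"subtype {lab} has < 2 samples")
    samples = list(labels.index)
    out = {}
    for name, mat in (("mrna", bundle.mrna), ("lnc", bundle.lnc)):
        table = de_mod.de_table(mat[samples], labels.astype(str), alpha=alpha, lfc=0.0)
        top = table.sort_values(["p", "t"]).head(top_n)
        sub = mat.loc[top.index, samples]
        sd = sub.std(axis=1, ddof=1).replace(0.0, 1.0)
        z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
        out[name] = {"table": top, "zscores": z}
    return out
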