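"""Per-sample immune characterization: single-sample gene-set variation
scores, marker-based cell-population scores, and between-subtype testing."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection, PipelineError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# GSVA-style scores
# ---------------------------------------------------------------------------

def _gaussian_kcdf(x: np.ndarray) -> np.ndarray:
    """Per-gene expression statistic: Gaussian-kernel cumulative density of
    each value against the gene's own cross-sample distribution, with
    bandwidth sd/4.  Constant genes get 0.5 everywhere."""
    n_genes, n_samples = x.shape
    sd = x.std(axis=1, ddof=1)
    h = np.where(sd > 0, sd / 4.0, 1.0)
    diff = (x[:, :, None] - x[:, None, :]) / h[:, None, None]
    z = stats.norm.cdf(diff).mean(axis=2)
    z[sd == 0, :] = 0.5
    return z


def _symmetrized_ranks(z: np.ndarray) -> np.ndarray:
    """Per sample, rank genes by the statistic (largest first) and fold the
    rank about the center: r -> |p/2 - r|."""
    n_genes = z.shape[0]
    # rank 1 = largest statistic; deterministic tie-break by row order
    order = np.argsort(-z, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(1, n_genes + 1)[:, None]
    np.put_along_axis(ranks, order, np.broadcast_to(rows, z.shape), axis=0)
    return np.abs(n_genes / 2.0 - ranks)


def gsva_scores(
    mrna_matrix: pd.DataFrame,
    gene_sets: GeneSetCollection,
    tau: float = 1.0,
    mode: str = "mxdiff",
) -> pd.DataFrame:
    """Sample x set matrix of single-sample enrichment scores.

    Per sample, genes are walked in decreasing order of the symmetrized rank
    statistic; set members step up by ``|rank|^tau`` (normalized), others
    step down by ``1/(p - m)``.  ``mode="mxdiff"`` reports the difference of
    the two extreme deviations, ``mode="absmax"`` the single extreme of the
    larger magnitude.
    """
    if mrna_matrix.shape[1] < 3:
        raise PipelineError("need >= 3 samples for the cross-sample density")
    if mode not in ("mxdiff", "absmax"):
        raise PipelineError(f"unknown GSVA mode {mode!r}")
    x = mrna_matrix.to_numpy(dtype=float)
    genes = np.array([str(g) for g in mrna_matrix.index])
    z = _gaussian_kcdf(x)
    r = _symmetrized_ranks(z)

    n_genes, n_samples = x.shape
    gene_index = {g: i for i, g in enumerate(genes)}
    scores: dict[str, np.ndarray] = {}
    # walk genes in decreasing order of the expression statistic, weighted by
    # the symmetrized rank; tie-break on gene id keeps the order deterministic
    id_rank = np.argsort(np.argsort(genes))
    order = np.lexsort((np.broadcast_to(id_rank[:, None], z.shape), -z), axis=0)
    r_sorted = np.take_along_axis(r, order, axis=0)
    for name in gene_sets.names():
        members = [gene_index[g] for g in gene_sets.sets[name] if g in gene_index]
        if not members:
            logger.info("set %s has no genes in the matrix; skipped", name)
            continue
        hit = np.zeros(n_genes, dtype=bool)
        hit[members] = True
        m = len(members)
        col_scores = np.empty(n_samples)
        for j in range(n_samples):
            hit_sorted = hit[order[:, j]]
            w = np.abs(r_sorted[:, j]) ** tau * hit_sorted
            sw = w.sum()
            inc = w / sw if sw > 0 else hit_sorted / m
            dec = 0.0 if n_genes == m else (~hit_sorted) / (n_genes - m)
            walk = np.cumsum(inc - dec)
            pos = max(walk.max(), 0.0)
            neg = min(walk.min(), 0.0)
            if mode == "mxdiff":
                col_scores[j] = pos + neg
            else:
                col_scores[j] = pos if pos >= -neg else neg
        scores[name] = col_scores
    return pd.DataFrame(scores, index=mrna_matrix.columns)


# ---------------------------------------------------------------------------
# marker-based cell scores
# ---------------------------------------------------------------------------

def cell_scores(
    mrna_matrix: pd.DataFrame, marker_sets: GeneSetCollection
) -> pd.DataFrame:
    """Sample x population matrix: arithmetic mean of detected marker
    log2 expression; populations with no detected marker are omitted."""
    present = set(map(str, mrna_matrix.index))
    out: dict[str, np.ndarray] = {}
    for name in marker_sets.names():
        detected = sorted(marker_sets.sets[name] & present)
        if not detected:
            logger.warning("population %s: no markers detected; omitted", name)
            continue
        out[name] = mrna_matrix.loc[detected].mean(axis=0).to_numpy()
    return pd.DataFrame(out, index=mrna_matrix.columns)


# ---------------------------------------------------------------------------
# between-subtype testing
# ---------------------------------------------------------------------------

def _wilcoxon_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p; exact distribution when group sizes are <= 10
    and there are no ties, mid-rank normal approximation otherwise."""
    if np.ptp(np.concatenate([a, b])) == 0:
        return float(len(a) * len(b)) / 2.0, 1.0
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_subtypes(
    profiles: pd.DataFrame,
    labels: pd.Series,
    feature_class: str | dict[str, str] = "pathway",
    alpha: float = 0.05,
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """Per-feature two-group test between the two subtypes.

    ``profiles`` is sample x feature; ``feature_class`` labels features as
    pathway/cell scores (single string or per-feature map).  Returns a table
    with columns feature, class, statistic, p, significant.
    """
    labels = pd.Series(labels)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise PipelineError(f"need exactly 2 subtype labels, got {uniq}")
    idx_a = labels.index[labels == uniq[0]]
    idx_b = labels.index[labels == uniq[1]]
    if min(len(idx_a), len(idx_b)) < 2:
        raise PipelineError("each subtype needs >= 2 samples")
    rows = []
    for feat in profiles.columns:
        a = profiles.loc[idx_a, feat].to_numpy(dtype=float)
        b = profiles.loc[idx_b, feat].to_numpy(dtype=float)
        if test == "wilcoxon":
            statistic, p = _wilcoxon_p(a, b)
        elif test == "ttest":
            res = stats.ttest_ind(a, b)
            statistic, p = float(res.statistic), float(res.pvalue)
        else:
            raise PipelineError(f"unknown test {test!r}")
        cls = feature_class if isinstance(feature_class, str) else feature_class.get(feat, "")
        rows.append(
            {"feature": feat, "class": cls, "statistic": statistic, "p": p,
             "significant": p < alpha}
        )
    return pd.DataFrame(rows)


def build_profiles(
    pathway_scores: pd.DataFrame | None,
    cell_score_matrix: pd.DataFrame | None,
    labels: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Join pathway and cell score matrices into one sample x feature frame
    plus a per-feature class map; optionally attaches subtype labels."""
    parts = []
    classes: dict[str, str] = {}
    if pathway_scores is not None and not pathway_scores.empty:
        parts.append(pathway_scores)
        classes.update({c: "pathway" for c in pathway_scores.columns})
    if cell_score_matrix is not None and not cell_score_matrix.empty:
        parts.append(cell_score_matrix)
        classes.update({c: "cell" for c in cell_score_matrix.columns})
    if not parts:
        return pd.DataFrame(), {}
    joined = pd.concat(parts, axis=1)
    if labels is not None:
        joined = joined.loc[labels.index]
        joined["subtype"] = labels
    return joined, classes
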