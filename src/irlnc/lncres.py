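"""Correlation-ranked gene-set enrichment per lncRNA and lncRES scoring.

For every lncRNA, all mRNAs are ranked by a rank score
``rs = -log10(p) * sign(cc)`` computed from the per-pair Pearson correlation,
and each gene set is tested for enrichment at the extremes of the ranked
list with a weighted Kolmogorov-Smirnov running sum.  The enrichment p-value
comes from a gene-label permutation null and is folded into
``lncres = 1 - 2p`` (ES > 0) or ``2p - 1`` (ES < 0); pairs with
``lncres > lncres_cut`` and BH FDR below ``fdr_cut`` are significant, and a
lncRNA with at least one significant pair is called immune-related.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .io import ExpressionBundle, GeneSetCollection, PipelineError

logger = logging.getLogger(__name__)


@dataclass
class LncresParams:
    method: str = "pearson"          # "pearson" | "spearman"
    p_min: float = 1e-300            # floor before the log10
    exponent: float = 1.0            # KS hit-weight exponent
    min_set_size: int = 5
    nperm: int = 1000
    seed: int = 0
    lncres_cut: float = 0.995
    fdr_cut: float = 0.05
    null_model: str = "sample"        # "sample" | "gene_label"
    null_pooling: str = "across_lnc"  # "across_lnc" | "per_lnc"
    fdr_scope: str = "global"         # "global" | "per_lnc"

    def validate(self) -> "LncresParams":
        if self.method not in ("pearson", "spearman"):
            raise PipelineError(f"unknown correlation method {self.method!r}")
        if self.nperm < 100:
            raise PipelineError("nperm must be >= 100")
        if self.null_model not in ("sample", "gene_label"):
            raise PipelineError(f"unknown null_model {self.null_model!r}")
        if self.null_pooling not in ("across_lnc", "per_lnc"):
            raise PipelineError(f"unknown null_pooling {self.null_pooling!r}")
        if self.fdr_scope not in ("global", "per_lnc"):
            raise PipelineError(f"unknown fdr_scope {self.fdr_scope!r}")
        return self


# ---------------------------------------------------------------------------
# correlation and rank scores
# ---------------------------------------------------------------------------

def correlate(
    lnc_matrix: pd.DataFrame,
    mrna_matrix: pd.DataFrame,
    method: str = "pearson",
    p_min: float = 1e-300,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs correlation and two-sided p-values (lncRNA x mRNA).

    ``p`` uses ``t = r * sqrt((n-2) / (1-r^2))`` on ``n-2`` degrees of
    freedom.  Zero-variance genes yield cc = 0, p = 1; perfect correlations
    are clamped to ``p_min``.
    """
    if list(lnc_matrix.columns) != list(mrna_matrix.columns):
        raise PipelineError("matrices are not sample-aligned")
    n = lnc_matrix.shape[1]
    if n < 4:
        raise PipelineError(f"need >= 4 shared samples, got {n}")

    x = lnc_matrix.to_numpy(dtype=float)
    y = mrna_matrix.to_numpy(dtype=float)
    if method == "spearman":
        x = stats.rankdata(x, axis=1)
        y = stats.rankdata(y, axis=1)
    elif method != "pearson":
        raise PipelineError(f"unknown correlation method {method!r}")

    def standardize(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        centered = a - a.mean(axis=1, keepdims=True)
        sd = np.sqrt((centered ** 2).sum(axis=1))
        ok = sd > 0
        z = np.where(ok[:, None], centered / np.where(ok, sd, 1.0)[:, None], 0.0)
        return z, ok

    zx, okx = standardize(x)
    zy, oky = standardize(y)
    cc = zx @ zy.T
    cc = np.clip(cc, -1.0, 1.0)
    degenerate = ~okx[:, None] | ~oky[None, :]
    cc[degenerate] = 0.0

    r2 = np.minimum(cc ** 2, 1.0 - 1e-16)
    tstat = np.abs(cc) * np.sqrt((n - 2) / (1.0 - r2))
    p = 2.0 * stats.t.sf(tstat, n - 2)
    p = np.clip(p, p_min, 1.0)
    p[degenerate] = 1.0
    idx, cols = lnc_matrix.index, mrna_matrix.index
    return (
        pd.DataFrame(cc, index=idx, columns=cols),
        pd.DataFrame(p, index=idx, columns=cols),
    )


def rank_score(cc, p, p_min: float = 1e-300):
    """``rs = -log10(p) * sign(cc)`` with p floored at ``p_min``."""
    cc_arr = np.asarray(cc, dtype=float)
    p_arr = np.clip(np.asarray(p, dtype=float), p_min, 1.0)
    rs = -np.log10(p_arr) * np.sign(cc_arr)
    if isinstance(cc, pd.DataFrame):
        return pd.DataFrame(rs, index=cc.index, columns=cc.columns)
    return rs if rs.shape else float(rs)


@dataclass
class RankedList:
    """mRNAs of one lncRNA ordered by descending rank score."""

    lnc_id: str
    genes: np.ndarray   # gene ids, descending rs, ties broken by gene id
    rs: np.ndarray      # aligned rank scores
    position: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.position:
            self.position = {g: i for i, g in enumerate(self.genes)}


def ranked_list(lnc_id: str, rs_row: pd.Series) -> RankedList:
    ids = rs_row.index.to_numpy(dtype=object)
    values = rs_row.to_numpy(dtype=float)
    order = np.lexsort((ids.astype(str), -values))
    return RankedList(lnc_id=lnc_id, genes=ids[order], rs=values[order])


# ---------------------------------------------------------------------------
# weighted KS enrichment
# ---------------------------------------------------------------------------

def _es_batch(
    positions: np.ndarray, weights: np.ndarray, n_total: int
) -> np.ndarray:
    """Signed-maximum-deviation ES for a batch of hit-position vectors.

    ``positions`` (B, m) must be sorted along axis 1; ``weights`` holds
    ``|rs|^exponent`` at those positions.  Hits increment by normalized
    weight, misses decrement by ``1/(N - m)``; all-zero weight rows fall back
    to uniform hit increments.
    """
    positions = np.atleast_2d(positions)
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    b, m = positions.shape
    miss_dec = 0.0 if n_total == m else 1.0 / (n_total - m)

    sw = weights.sum(axis=1, keepdims=True)
    uniform = np.full((b, m), 1.0 / m)
    cumw = np.where(sw > 0, np.cumsum(weights, axis=1) / np.where(sw > 0, sw, 1.0),
                    np.cumsum(uniform, axis=1))
    j = np.arange(m)[None, :]
    misses_before = (positions - j) * miss_dec
    r_after = cumw - misses_before
    r_before = np.concatenate([np.zeros((b, 1)), cumw[:, :-1]], axis=1) - misses_before
    max_dev = np.maximum(r_after.max(axis=1), 0.0)
    min_dev = np.minimum(r_before.min(axis=1), 0.0)
    return np.where(max_dev >= -min_dev, max_dev, min_dev)


def gsea_es(
    ranked: RankedList, gene_set, exponent: float = 1.0
) -> float:
    """Weighted KS enrichment score of *gene_set* on a ranked list."""
    hits = sorted(ranked.position[g] for g in gene_set if g in ranked.position)
    if not hits:
        raise PipelineError("gene set has empty intersection with the ranked list")
    pos = np.asarray(hits, dtype=int)
    w = np.abs(ranked.rs[pos]) ** exponent
    return float(_es_batch(pos[None, :], w[None, :], len(ranked.genes))[0])


def running_sum(ranked: RankedList, gene_set, exponent: float = 1.0) -> np.ndarray:
    """The full KS running sum (for inspection/plots); O(N)."""
    n = len(ranked.genes)
    hit = np.isin(ranked.genes, list(gene_set))
    nh = int(hit.sum())
    if nh == 0:
        raise PipelineError("gene set has empty intersection with the ranked list")
    w = np.abs(ranked.rs) ** exponent * hit
    sw = w.sum()
    inc = w / sw if sw > 0 else hit / nh
    dec = np.where(hit, 0.0, 0.0 if n == nh else 1.0 / (n - nh))
    return np.cumsum(inc - dec)


def null_es(
    weights_sorted: np.ndarray,
    set_size: int,
    nperm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gene-label permutation null: ES of ``nperm`` random sets of the given
    size drawn uniformly from the list positions."""
    n = weights_sorted.size
    if set_size > n:
        raise PipelineError("set size exceeds list length")
    keys = rng.random((nperm, n))
    pos = np.sort(np.argpartition(keys, set_size - 1, axis=1)[:, :set_size], axis=1)
    return _es_batch(pos, weights_sorted[pos], n)


class NullCounter:
    """Sorted-null lookup giving the same p as :func:`empirical_p`."""

    def __init__(self, null: np.ndarray):
        self.pos = np.sort(null[null > 0])
        self.neg = np.sort(null[null < 0])

    def p(self, es: float) -> float:
        if es > 0:
            count = self.pos.size - np.searchsorted(self.pos, es, side="left")
            return (1.0 + count) / (1.0 + self.pos.size)
        if es < 0:
            count = np.searchsorted(self.neg, es, side="right")
            return (1.0 + count) / (1.0 + self.neg.size)
        return 1.0


def empirical_p(es: float, null: np.ndarray) -> float:
    """Sign-matched permutation p: ``(1 + #{|es*| >= |es|, same sign}) /
    (1 + #{same sign})``; ES = 0 gives p = 1."""
    if es > 0:
        same = null[null > 0]
        return (1.0 + float((same >= es).sum())) / (1.0 + same.size)
    if es < 0:
        same = null[null < 0]
        return (1.0 + float((same <= es).sum())) / (1.0 + same.size)
    return 1.0


def gsea_p(
    ranked: RankedList,
    gene_set,
    es: float,
    nperm: int = 1000,
    seed: int = 0,
    exponent: float = 1.0,
) -> float:
    """Permutation p-value for one (ranked list, gene set) pair."""
    if nperm < 100:
        raise PipelineError("nperm must be >= 100")
    m = sum(1 for g in gene_set if g in ranked.position)
    if m == 0:
        raise PipelineError("gene set has empty intersection with the ranked list")
    rng = np.random.default_rng(seed)
    w = np.abs(ranked.rs) ** exponent
    return empirical_p(es, null_es(w, m, nperm, rng))


def lncres_transform(es, p):
    """``1 - 2p`` for ES > 0, ``2p - 1`` for ES < 0, 0 for ES = 0."""
    es_arr = np.asarray(es, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise PipelineError("p must lie in [0, 1]")
    out = np.where(es_arr > 0, 1.0 - 2.0 * p_arr,
                   np.where(es_arr < 0, 2.0 * p_arr - 1.0, 0.0))
    return float(out) if out.shape == () else out


# ---------------------------------------------------------------------------
# full scoring
# ---------------------------------------------------------------------------

def sample_null_es(
    lnc_values: np.ndarray,
    mrna_z: np.ndarray,
    member_cols: dict[str, np.ndarray],
    nperm: int,
    rng: np.random.Generator,
    exponent: float = 1.0,
    p_min: float = 1e-300,
) -> dict[str, np.ndarray]:
    """Sample-permutation null: permute the lncRNA's expression across
    samples, re-correlate, re-rank, and recompute the ES of every set.

    Unlike the gene-label null this preserves the inter-mRNA correlation
    structure, so coherent co-expression modules do not inflate the
    significance of unrelated lncRNAs.  ``mrna_z`` holds row-standardized
    mRNA expression (genes x samples); ``member_cols`` maps set name ->
    mRNA row indices.
    """
    n = lnc_values.size
    n_genes = mrna_z.shape[0]
    union = np.unique(np.concatenate(list(member_cols.values())))
    upos = {g: i for i, g in enumerate(union)}
    setcols = {k: np.array([upos[i] for i in v]) for k, v in member_cols.items()}

    x = rng.permuted(np.tile(lnc_values, (nperm, 1)), axis=1)
    x = x - x.mean(axis=1, keepdims=True)
    sd = np.sqrt((x ** 2).sum(axis=1, keepdims=True))
    x = np.divide(x, sd, out=np.zeros_like(x), where=sd > 0)
    r = np.clip(x @ mrna_z.T, -1.0, 1.0)

    # ranking by descending rank score == ranking by descending r
    keys = np.sort(-r, axis=1)
    r_mem = r[:, union]
    tstat = np.abs(r_mem) * np.sqrt((n - 2) / (1.0 - np.minimum(r_mem ** 2, 1 - 1e-16)))
    w_mem = -np.log10(np.clip(2.0 * stats.t.sf(tstat, n - 2), p_min, 1.0))
    if exponent != 1.0:
        w_mem = w_mem ** exponent
    pos = np.empty(r_mem.shape, dtype=np.int64)
    for i in range(nperm):
        pos[i] = np.searchsorted(keys[i], -r[i, union], side="left")
    out: dict[str, np.ndarray] = {}
    for name, cols in setcols.items():
        pk, wk = pos[:, cols], w_mem[:, cols]
        order = np.argsort(pk, axis=1)
        out[name] = _es_batch(
            np.take_along_axis(pk, order, axis=1),
            np.take_along_axis(wk, order, axis=1),
            n_genes,
        )
    return out


def score_all(
    bundle: ExpressionBundle,
    gene_sets: GeneSetCollection,
    params: LncresParams | None = None,
) -> pd.DataFrame:
    """Score every (lncRNA, gene set) pair; returns the enrichment table.

    Columns: lnc, set, category, size, es, p, lncres, fdr, significant.
    Two permutation nulls are available: ``null_model="sample"`` (default)
    permutes each lncRNA across samples and preserves mRNA co-expression;
    ``"gene_label"`` draws random sets of matched size on the fixed ranked
    list.  Nulls are pooled across lncRNAs by default
    (``null_pooling="across_lnc"``), which sharpens the p-value resolution
    beyond ``1/nperm``.
    """
    params = (params or LncresParams()).validate()
    cc, pmat = correlate(bundle.lnc, bundle.mrna, params.method, params.p_min)
    rs = rank_score(cc, pmat, params.p_min)

    universe = set(map(str, bundle.mrna.index))
    restricted = gene_sets.restrict(universe, params.min_set_size)
    set_names = restricted.names()
    if not set_names:
        return _empty_records()

    rng = np.random.default_rng(params.seed)
    rows: list[dict] = []
    for lnc_id in rs.index:
        ranked = ranked_list(str(lnc_id), rs.loc[lnc_id])
        for name in set_names:
            members = restricted.sets[name]
            rows.append(
                {
                    "lnc": str(lnc_id),
                    "set": name,
                    "category": restricted.category.get(name, name),
                    "size": len(members),
                    "es": gsea_es(ranked, members, params.exponent),
                }
            )
    records = pd.DataFrame(rows)

    if params.null_model == "sample":
        y = bundle.mrna.to_numpy(dtype=float)
        if params.method == "spearman":
            y = stats.rankdata(y, axis=1)
        yc = y - y.mean(axis=1, keepdims=True)
        ysd = np.sqrt((yc ** 2).sum(axis=1, keepdims=True))
        mrna_z = np.divide(yc, ysd, out=np.zeros_like(yc), where=ysd > 0)
        mrna_row = {str(g): i for i, g in enumerate(bundle.mrna.index)}
        member_cols = {
            name: np.array(sorted(mrna_row[g] for g in restricted.sets[name]))
            for name in set_names
        }
        null_by_set: dict[str, list[np.ndarray]] = {name: [] for name in set_names}
        per_lnc_set_null: list[dict[str, np.ndarray]] = []
        for lnc_id in bundle.lnc.index:
            vals = bundle.lnc.loc[lnc_id].to_numpy(dtype=float)
            if params.method == "spearman":
                vals = stats.rankdata(vals)
            nulls = sample_null_es(
                vals, mrna_z, member_cols, params.nperm, rng,
                params.exponent, params.p_min,
            )
            per_lnc_set_null.append(nulls)
            for name in set_names:
                null_by_set[name].append(nulls[name])
        if params.null_pooling == "across_lnc":
            counters = {
                name: NullCounter(np.concatenate(chunks))
                for name, chunks in null_by_set.items()
            }
            records["p"] = [counters[r.set].p(r.es) for r in records.itertuples()]
        else:
            lnc_index = {str(l): i for i, l in enumerate(bundle.lnc.index)}
            records["p"] = [
                empirical_p(r.es, per_lnc_set_null[lnc_index[r.lnc]][r.set])
                for r in records.itertuples()
            ]
    else:
        sizes = sorted({len(restricted.sets[s]) for s in set_names})
        nulls_by_size: dict[int, list[np.ndarray]] = {m: [] for m in sizes}
        per_lnc_null: list[dict[int, np.ndarray]] = []
        for lnc_id in rs.index:
            ranked = ranked_list(str(lnc_id), rs.loc[lnc_id])
            w = np.abs(ranked.rs) ** params.exponent
            lnc_nulls = {m: null_es(w, m, params.nperm, rng) for m in sizes}
            per_lnc_null.append(lnc_nulls)
            for m in sizes:
                nulls_by_size[m].append(lnc_nulls[m])
        if params.null_pooling == "across_lnc":
            counters = {
                m: NullCounter(np.concatenate(chunks))
                for m, chunks in nulls_by_size.items()
            }
            records["p"] = [counters[r.size].p(r.es) for r in records.itertuples()]
        else:
            lnc_index = {str(l): i for i, l in enumerate(rs.index)}
            records["p"] = [
                empirical_p(r.es, per_lnc_null[lnc_index[r.lnc]][r.size])
                for r in records.itertuples()
            ]

    records["lncres"] = lncres_transform(records["es"].to_numpy(), records["p"].to_numpy())
    if params.fdr_scope == "global":
        records["fdr"] = bh_adjust(records["p"].to_numpy())
    else:
        records["fdr"] = records.groupby("lnc")["p"].transform(
            lambda s: bh_adjust(s.to_numpy())
        )
    records["significant"] = (records["lncres"] > params.lncres_cut) & (
        records["fdr"] < params.fdr_cut
    )
    return records


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["lnc", "set", "category", "size", "es", "p", "lncres", "fdr", "significant"]
    )


def immune_lncrnas(records: pd.DataFrame) -> list[str]:
    """lncRNAs with at least one significant enrichment record, sorted."""
    if records.empty:
        return []
    return sorted(records.loc[records["significant"], "lnc"].unique())


def intersect_with_de(immune_lnc_ids, de_lnc_ids) -> dict:
    """Sorted intersection plus Venn counts of the two id sets."""
    a, b = set(immune_lnc_ids), set(de_lnc_ids)
    overlap = sorted(a & b)
    return {
        "overlap": overlap,
        "n_immune": len(a),
        "n_de": len(b),
        "n_overlap": len(overlap),
    }


def overlap_validation(records_a: pd.DataFrame, records_b: pd.DataFrame) -> dict:
    """Cross-dataset agreement: Jaccard of significant lncRNA sets and
    Spearman correlation of lncRES over shared (lnc, set) pairs."""
    sig_a = set(immune_lncrnas(records_a))
    sig_b = set(immune_lncrnas(records_b))
    union = sig_a | sig_b
    jaccard = len(sig_a & sig_b) / len(union) if union else 1.0
    merged = records_a.merge(records_b, on=["lnc", "set"], suffixes=("_a", "_b"))
    if len(merged) >= 3 and merged["lncres_a"].nunique() > 1 and merged["lncres_b"].nunique() > 1:
        rank_r = float(stats.spearmanr(merged["lncres_a"], merged["lncres_b"]).statistic)
    else:
        rank_r = float("nan")
    return {
        "jaccard": jaccard,
        "n_significant_a": len(sig_a),
        "n_significant_b": len(sig_b),
        "n_shared_pairs": int(len(merged)),
        "lncres_rank_correlation": rank_r,
    }
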