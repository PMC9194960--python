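"""Two-group differential expression with empirical-Bayes variance
moderation (a re-implementation of the moderated t-statistic).

The prior degrees of freedom ``d0`` and prior variance ``s0²`` are estimated
by matching the first two moments of ``log(s²)`` to a scaled log-F
distribution (digamma/trigamma inversion); the posterior variance shrinks
each gene's residual variance toward the prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ExpressionBundle, PipelineError


@dataclass
class EBayesFit:
    d0: float                 # prior degrees of freedom (may be inf)
    s0_sq: float              # prior variance
    s2_post: np.ndarray       # posterior (moderated) variances
    t: np.ndarray             # moderated t-statistics
    p: np.ndarray             # two-sided p-values
    df_total: float           # residual df + prior df


def fit_two_group(
    matrix: pd.DataFrame, groups: pd.Series | dict
) -> pd.DataFrame:
    """Per-gene mean difference and pooled residual variance.

    ``groups`` maps sample id -> group label; exactly two labels are
    expected.  The log2 fold change is mean(second) - mean(first) with labels
    ordered so that ``pulpitis``/``normal`` gives pulpitis minus normal when
    both are present, otherwise lexicographic.
    """
    groups = pd.Series(groups)
    groups = groups.loc[[s for s in matrix.columns if s in groups.index]]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise PipelineError(f"need exactly 2 groups, got {labels}")
    if "normal" in labels and "pulpitis" in labels:
        labels = ["normal", "pulpitis"]
    ref, alt = labels
    cols_ref = groups.index[groups == ref]
    cols_alt = groups.index[groups == alt]
    n1, n2 = len(cols_ref), len(cols_alt)
    if min(n1, n2) < 2:
        raise PipelineError(f"group with < 2 samples: {ref}={n1}, {alt}={n2}")

    x1 = matrix[cols_ref].to_numpy(dtype=float)
    x2 = matrix[cols_alt].to_numpy(dtype=float)
    log2fc = x2.mean(axis=1) - x1.mean(axis=1)
    s2 = ((x1.var(axis=1, ddof=1) * (n1 - 1)) + (x2.var(axis=1, ddof=1) * (n2 - 1))) / (
        n1 + n2 - 2
    )
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "s2": s2,
            "df": float(n1 + n2 - 2),
            "stdev_coef": np.sqrt(1.0 / n1 + 1.0 / n2),
        },
        index=matrix.index,
    )


def _trigamma_inverse(y: np.ndarray | float) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    x = np.where(y > 1e7, 1.0 / np.sqrt(y), 0.5 + 1.0 / y)
    for _ in range(60):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif / x) < 1e-10):
            break
    return x if x.shape != (1,) else float(x[0])


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log(s2) to its scaled log-F distribution -> (d0, s0²).

    Returns ``d0 = inf`` when the ensemble variance of log(s2) does not
    exceed trigamma(df/2), i.e. no excess dispersion beyond sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 10:
        raise PipelineError("need >= 10 genes to estimate the variance prior")
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise PipelineError("all residual variances are zero; degenerate ensemble")
    # tiny offset keeps zero-variance genes in the ensemble without -inf logs
    floor = positive.min() * 1e-6
    z = np.log(np.maximum(s2, floor))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * float(_trigamma_inverse(excess))
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def ebayes_moderate(
    log2fc: np.ndarray,
    s2: np.ndarray,
    df: float,
    stdev_coef: np.ndarray | float,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> EBayesFit:
    """Moderated t-statistics and p-values from shrunken variances.

    ``d0``/``s0_sq`` may be supplied to bypass estimation (``d0=0`` gives the
    ordinary t-statistic; ``d0=inf`` gives a constant posterior variance).
    """
    log2fc = np.asarray(log2fc, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if d0 is None or s0_sq is None:
        d0_est, s0_est = fit_f_dist(s2, df)
        d0 = d0_est if d0 is None else d0
        s0_sq = s0_est if s0_sq is None else s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post) * stdev_coef
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return EBayesFit(d0=float(d0), s0_sq=float(s0_sq), s2_post=s2_post, t=t,
                     p=p, df_total=float(df_total))


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise PipelineError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


def de_table(
    matrix: pd.DataFrame,
    groups: pd.Series | dict,
    alpha: float = 0.05,
    lfc: float = 1.0,
    moderated: bool = True,
) -> pd.DataFrame:
    """Full differential-expression table for one matrix.

    Columns: gene, log2fc, s2, t, p, adj_p, significant, direction.
    """
    fit = fit_two_group(matrix, groups)
    df = float(fit["df"].iloc[0])
    d0 = None if moderated else 0.0
    s0 = None if moderated else 0.0
    eb = ebayes_moderate(
        fit["log2fc"].to_numpy(), fit["s2"].to_numpy(), df,
        fit["stdev_coef"].to_numpy(), d0=d0, s0_sq=s0,
    )
    adj = bh_adjust(eb.p)
    out = pd.DataFrame(
        {
            "gene": fit.index,
            "log2fc": fit["log2fc"].to_numpy(),
            "s2": fit["s2"].to_numpy(),
            "t": eb.t,
            "p": eb.p,
            "adj_p": adj,
            "significant": (adj < alpha) & (np.abs(fit["log2fc"].to_numpy()) >= lfc),
            "direction": np.where(fit["log2fc"].to_numpy() >= 0, "up", "down"),
        }
    ).set_index("gene")
    out.attrs["d0"] = eb.d0
    out.attrs["s0_sq"] = eb.s0_sq
    return out


def select_de(results: pd.DataFrame, alpha: float = 0.05, lfc: float = 1.0) -> list[str]:
    """Genes with adj_p < alpha and |log2fc| >= lfc, sorted by (p, gene)."""
    hits = results[(results["adj_p"] < alpha) & (results["log2fc"].abs() >= lfc)]
    hits = hits.assign(_gene=hits.index.astype(str)).sort_values(["p", "_gene"])
    return list(hits.index)


def de_both(
    bundle: ExpressionBundle, alpha: float = 0.05, lfc: float = 1.0,
    moderated: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DE tables for (mRNA, lncRNA) between normal and pulpitis."""
    groups = bundle.design["condition"]
    return (
        de_table(bundle.mrna, groups, alpha, lfc, moderated),
        de_table(bundle.lnc, groups, alpha, lfc, moderated),
    )
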