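"""Readers and writers for expression matrices, design tables and GMT gene
sets, plus the precleaning applied before analysis.

Expression matrices are tab-separated text with genes in rows (first column =
gene id) and one column per sample, values on log2 scale after precleaning.
The design table is a TSV with columns ``sample_id``, ``condition`` and an
optional ``dataset`` tag; conditions are ``normal`` and ``pulpitis``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("normal", "pulpitis")


class PipelineError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(PipelineError):
    """An invalid configuration value or combination."""


class FormatError(PipelineError):
    """A file did not conform to the expected text format."""


@dataclass
class ExpressionBundle:
    """Paired lncRNA and mRNA log2 expression with the sample design.

    Both matrices are gene-by-sample :class:`pandas.DataFrame` objects whose
    columns are identical and identically ordered, matching the design index.
    """

    lnc: pd.DataFrame
    mrna: pd.DataFrame
    design: pd.DataFrame

    def validate(self) -> "ExpressionBundle":
        for name, mat in (("lnc", self.lnc), ("mrna", self.mrna)):
            if mat.index.has_duplicates:
                dups = mat.index[mat.index.duplicated()].unique().tolist()
                raise FormatError(f"duplicate gene ids in {name} matrix: {dups[:5]}")
            if list(mat.columns) != list(self.design.index):
                missing = sorted(set(self.design.index) ^ set(mat.columns))
                raise FormatError(
                    f"sample mismatch between {name} matrix and design: {missing}"
                )
            if mat.isna().any().any():
                raise FormatError(f"missing values present in {name} matrix")
        if "condition" not in self.design.columns:
            raise FormatError("design table lacks a 'condition' column")
        bad = set(self.design["condition"]) - set(CONDITIONS)
        if bad:
            raise FormatError(f"unknown conditions in design: {sorted(bad)}")
        counts = self.design["condition"].value_counts()
        for cond in CONDITIONS:
            if counts.get(cond, 0) < 2:
                raise FormatError(f"fewer than 2 samples with condition '{cond}'")
        return self

    @property
    def samples(self) -> list[str]:
        return list(self.design.index)

    def samples_where(self, condition: str) -> list[str]:
        return list(self.design.index[self.design["condition"] == condition])

    def subset_samples(self, samples: list[str]) -> "ExpressionBundle":
        return ExpressionBundle(
            lnc=self.lnc[samples], mrna=self.mrna[samples],
            design=self.design.loc[samples],
        )


@dataclass
class GeneSetCollection:
    """Named gene sets with category labels, GMT-backed."""

    sets: dict[str, frozenset[str]]
    category: dict[str, str] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set '{name}' is empty")
        for name in self.sets:
            self.category.setdefault(name, name)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def restrict(self, universe: set[str], min_size: int = 1) -> "GeneSetCollection":
        """Intersect every set with *universe*, dropping sets below *min_size*."""
        kept = {}
        for name, members in self.sets.items():
            inter = frozenset(members & universe)
            if len(inter) >= min_size:
                kept[name] = inter
            else:
                logger.info("gene set %s dropped (%d genes in matrix)", name, len(inter))
        return GeneSetCollection(
            sets=kept,
            category={n: self.category[n] for n in kept},
            provenance=self.provenance,
        )


# ---------------------------------------------------------------------------
# expression / design readers
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample TSV; first column holds gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "gene_id") -> None:
    # %.17g round-trips float64 exactly
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.17g")


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "condition" not in df.columns:
        raise FormatError(f"{path}: design needs 'sample_id' and 'condition' columns")
    return df.set_index("sample_id")


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index_label="sample_id")


def _collapse_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    """Keep, for each duplicated gene id, the row with the largest mean."""
    if not df.index.has_duplicates:
        return df
    means = df.mean(axis=1)
    order = np.argsort(-means.to_numpy(), kind="stable")
    deduped = df.iloc[order]
    deduped = deduped[~deduped.index.duplicated(keep="first")]
    logger.info("collapsed %d duplicate gene rows", len(df) - len(deduped))
    return deduped.loc[sorted(deduped.index)]


def read_expression(
    expr_path: str | Path,
    design_path: str | Path,
    biotype_map: dict[str, str],
) -> ExpressionBundle:
    """Read a combined expression TSV and split it by biotype.

    ``biotype_map`` maps each gene id to ``"lncRNA"`` or ``"mRNA"``; unmapped
    ids are dropped with a logged count.  Duplicate gene ids are collapsed to
    the row with the largest mean expression.
    """
    mat = read_matrix(expr_path)
    design = read_design(design_path)
    missing = sorted(set(design.index) - set(mat.columns))
    if missing:
        raise FormatError(f"samples in design but not in matrix: {missing}")
    extra = sorted(set(mat.columns) - set(design.index))
    if extra:
        raise FormatError(f"samples in matrix but not in design: {extra}")
    mat = mat[list(design.index)]

    unmapped = [g for g in mat.index if g not in biotype_map]
    if unmapped:
        logger.info("dropping %d gene ids without a biotype", len(unmapped))
        mat = mat.drop(index=unmapped)
    biotypes = pd.Series({g: biotype_map[g] for g in mat.index})
    lnc = _collapse_duplicates(mat.loc[biotypes[biotypes == "lncRNA"].index.unique()])
    mrna = _collapse_duplicates(mat.loc[biotypes[biotypes == "mRNA"].index.unique()])
    return ExpressionBundle(lnc=lnc, mrna=mrna, design=design).validate()


def read_bundle(
    lnc_path: str | Path, mrna_path: str | Path, design_path: str | Path
) -> ExpressionBundle:
    """Read a bundle stored as separate lncRNA / mRNA matrices."""
    design = read_design(design_path)
    parts = []
    for path in (lnc_path, mrna_path):
        mat = read_matrix(path)
        missing = sorted(set(design.index) - set(mat.columns))
        if missing:
            raise FormatError(f"{path}: samples missing from matrix: {missing}")
        parts.append(_collapse_duplicates(mat[list(design.index)]))
    return ExpressionBundle(lnc=parts[0], mrna=parts[1], design=design).validate()


# ---------------------------------------------------------------------------
# precleaning
# ---------------------------------------------------------------------------

LOG_DETECTION_MAX = 50.0


def _preclean_matrix(mat: pd.DataFrame, min_iqr: float, label: str) -> pd.DataFrame:
    n_na = int(mat.isna().any(axis=1).sum())
    if n_na:
        logger.warning("%s: dropping %d rows with missing values", label, n_na)
        mat = mat.dropna(axis=0)
    if mat.size and float(mat.to_numpy().max()) > LOG_DETECTION_MAX:
        logger.info("%s: max > %g, applying log2(x+1)", label, LOG_DETECTION_MAX)
        mat = np.log2(mat.clip(lower=0) + 1.0)
    if min_iqr > 0:
        q3 = mat.quantile(0.75, axis=1)
        q1 = mat.quantile(0.25, axis=1)
        keep = (q3 - q1) >= min_iqr
        dropped = int((~keep).sum())
        if dropped:
            logger.info("%s: removing %d low-IQR rows", label, dropped)
        mat = mat.loc[keep]
    if mat.empty:
        raise FormatError(f"{label}: no genes left after precleaning")
    return mat.loc[sorted(mat.index)]


def quantile_normalize(mat: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization across samples (mean of sorted values)."""
    arr = mat.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0)
    ranks = np.empty_like(order)
    rows = np.arange(arr.shape[0])[:, None]
    ranks[order, np.arange(arr.shape[1])[None, :]] = rows
    reference = np.sort(arr, axis=0).mean(axis=1)
    return pd.DataFrame(reference[ranks], index=mat.index, columns=mat.columns)


def preclean(
    bundle: ExpressionBundle,
    min_iqr: float = 0.0,
    quantile: bool = False,
) -> ExpressionBundle:
    """Precleaning: optional log2 transform (when max > 50), missing-value row
    drop, low-IQR row filter, deterministic (lexicographic) row order and
    optional quantile normalization.  Idempotent for fixed parameters."""
    lnc = _preclean_matrix(bundle.lnc, min_iqr, "lnc")
    mrna = _preclean_matrix(bundle.mrna, min_iqr, "mrna")
    if quantile:
        lnc = quantile_normalize(lnc)
        mrna = quantile_normalize(mrna)
    return replace(bundle, lnc=lnc, mrna=mrna).validate()


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``"""
    sets: dict[str, frozenset[str]] = {}
    category: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if len(genes) != len(fields) - 2:
                raise FormatError(f"{path}:{lineno}: empty gene field")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name '{name}'")
            sets[name] = frozenset(genes)
            category[name] = description
    return GeneSetCollection(sets=sets, category=category, provenance=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            genes = sorted(collection.sets[name])
            fh.write("\t".join([name, collection.category.get(name, name), *genes]) + "\n")
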