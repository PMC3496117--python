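"""Differential-expression gene selection for two-color array designs.

The input is a genes × samples matrix of strictly positive,
background-corrected intensities together with a per-sample design table
(cell ``line`` — resistant vs control — plus ``dye`` and ``array``, the
natural nuisance factors of a two-color hybridization).  Per gene, a
main-effects ANOVA on the log2 scale::

    log2(intensity) ~ line + dye + array

yields the line-effect contrast (the log2 fold change, resistant minus
control) and an F-test p-value for the line term.  The moment estimators
used by commercial array suites coincide with ordinary least squares on
balanced designs, which the synthetic designs are by construction, so the
model is fitted by OLS.  Genes are then selected by a fold-change
threshold (>2-fold by default) combined with Benjamini–Hochberg FDR
control (0.05 by default, 0.01 for a stricter list).

When several probe rows share a gene symbol, the row with the largest
absolute log2 fold change represents the gene (common Agilent practice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import normalize_symbol

__all__ = [
    "ExpressionMatrix",
    "DEGeneSet",
    "fit_gene_anova",
    "bh_fdr",
    "select_de_genes",
    "load_expression",
    "load_design",
]

_LOG = logging.getLogger(__name__)

LINE_FACTORS = ("line", "dye", "array")
_RSS_REL_TOL = 1e-12  # residual sums below this fraction of total SS count as zero


@dataclass
class ExpressionMatrix:
    """Background-corrected intensity matrix plus the sample design table.

    ``values``: DataFrame indexed by gene symbol, columns = sample ids,
    strictly positive intensities.  ``design``: DataFrame indexed by
    sample id with columns ``line``, ``dye``, ``array``.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.copy()
        self.values.index = [normalize_symbol(g) for g in self.values.index]
        if not np.all(self.values.to_numpy() > 0):
            raise ValueError("intensities must be strictly positive")
        missing = [c for c in LINE_FACTORS if c not in self.design.columns]
        if missing:
            raise ValueError(f"design table missing factor column(s): {missing}")
        if not set(self.values.columns) <= set(self.design.index):
            uncovered = sorted(set(self.values.columns) - set(self.design.index))
            raise ValueError(f"design does not cover sample(s): {uncovered[:5]}")
        self.design = self.design.loc[list(self.values.columns), list(LINE_FACTORS)]
        counts = self.design["line"].value_counts()
        if len(counts) < 2:
            raise ValueError("design needs two line levels (resistant and control)")
        if counts.min() < 2:
            raise ValueError("need at least 2 samples per line level")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DEGeneSet:
    """Per-gene DE statistics with the selection thresholds applied.

    ``table`` columns: gene, log2fc, p, q, selected.  ``selected`` genes
    satisfy |fold change| > ``fc_min`` (a linear fold, default 2.0) and
    q ≤ ``fdr_max``.
    """

    table: pd.DataFrame
    fc_min: float = 2.0
    fdr_max: float = 0.05

    @property
    def selected(self) -> frozenset[str]:
        return frozenset(self.table.loc[self.table["selected"], "gene"])

    @property
    def log2fc(self) -> pd.Series:
        return self.table.set_index("gene")["log2fc"]

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ----------------------------------------------------------------------
# model fitting


def _dummy_columns(values: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded dummies, reference = first sorted level."""
    levels = sorted(set(values))
    cols = []
    names = []
    for lev in levels[1:]:
        cols.append((values == lev).to_numpy(dtype=float))
        names.append(str(lev))
    if cols:
        return np.column_stack(cols), names
    return np.empty((len(values), 0)), names


def _design_matrices(design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, str]:
    """Full and line-reduced design matrices for the main-effects model.

    The line factor is coded so the coefficient is resistant minus
    control: ``control`` is the reference when present, otherwise the
    lexicographically smaller level.
    """
    line = design["line"].astype(str)
    levels = sorted(set(line))
    if len(levels) != 2:
        raise ValueError(f"line factor must have exactly 2 levels, got {levels}")
    ref = "control" if "control" in levels else levels[0]
    eff = [l for l in levels if l != ref][0]
    line_col = (line == eff).to_numpy(dtype=float)[:, None]

    n = len(design)
    blocks = [np.ones((n, 1))]
    for factor in ("dye", "array"):
        cols, _ = _dummy_columns(design[factor].astype(str))
        blocks.append(cols)
    x_reduced = np.column_stack(blocks)
    x_full = np.column_stack([x_reduced[:, :1], line_col, x_reduced[:, 1:]])
    return x_full, x_reduced, eff


def _fit_all_genes(mat: ExpressionMatrix) -> pd.DataFrame:
    """Vectorized per-gene OLS ANOVA: log2fc and line-effect F-test p.

    All genes share the design matrix, so a single least-squares solve
    handles the whole matrix; the F statistic for the line term is formed
    from the residual sums of the full and line-reduced fits.
    """
    x_full, x_reduced, _ = _design_matrices(mat.design)
    y = np.log2(mat.values.to_numpy(dtype=float)).T  # samples × genes

    n = x_full.shape[0]
    rank_full = np.linalg.matrix_rank(x_full)
    df_resid = n - rank_full
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom in the ANOVA model")

    beta_full, *_ = np.linalg.lstsq(x_full, y, rcond=None)
    beta_red, *_ = np.linalg.lstsq(x_reduced, y, rcond=None)
    rss_full = np.sum((y - x_full @ beta_full) ** 2, axis=0)
    rss_red = np.sum((y - x_reduced @ beta_red) ** 2, axis=0)

    log2fc = beta_full[1]
    total_ss = np.maximum(np.sum((y - y.mean(axis=0)) ** 2, axis=0), 1.0)
    tiny = _RSS_REL_TOL * total_ss
    delta = np.maximum(rss_red - rss_full, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = delta / (rss_full / df_resid)
    pvals = stats.f.sf(f_stat, 1, df_resid)
    # saturated fits: no residual variation left
    zero_resid = rss_full <= tiny
    pvals = np.where(zero_resid & (delta <= tiny), 1.0, pvals)
    pvals = np.where(zero_resid & (delta > tiny), 0.0, pvals)

    return pd.DataFrame(
        {"gene": mat.genes, "log2fc": log2fc, "p": pvals}
    )


def fit_gene_anova(mat: ExpressionMatrix, gene: str) -> tuple[float, float]:
    """Line-effect log2 fold change and F-test p-value for one gene.

    Fits ``log2(intensity) ~ line + dye + array`` by OLS (equivalent to
    the moment estimators on balanced designs) and tests the line term.
    """
    gene = normalize_symbol(gene)
    if gene not in set(mat.values.index):
        raise KeyError(f"gene {gene!r} not in expression matrix")
    sub = ExpressionMatrix.__new__(ExpressionMatrix)
    sub.values = mat.values.loc[[gene]].iloc[[0]]
    sub.design = mat.design
    row = _fit_all_genes(sub).iloc[0]
    return float(row["log2fc"]), float(row["p"])


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    q_(i) = min_{j ≥ i} p_(j) · m / j, clipped to 1; monotone
    nondecreasing in p-value rank by construction.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, *_ = multipletests(p, method="fdr_bh")
    return q


def select_de_genes(
    mat: ExpressionMatrix, fc_min: float = 2.0, fdr_max: float = 0.05
) -> DEGeneSet:
    """Full DE filter chain: per-gene ANOVA → BH FDR → fold & FDR thresholds.

    ``fc_min`` is a linear fold change (2.0 means |log2fc| > 1).
    Duplicate gene symbols are collapsed to the row with the largest
    |log2fc| before FDR correction.
    """
    if fc_min <= 0 or fdr_max <= 0:
        raise ValueError("thresholds must be positive")
    table = _fit_all_genes(mat)
    # probe → gene collapsing: keep the most responsive row per symbol
    table = (
        table.assign(_absfc=table["log2fc"].abs())
        .sort_values(["_absfc", "p"], ascending=[False, True], kind="mergesort")
        .drop_duplicates("gene", keep="first")
        .drop(columns="_absfc")
        .sort_values("gene", kind="mergesort")
        .reset_index(drop=True)
    )
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["selected"] = (np.abs(table["log2fc"]) > np.log2(fc_min)) & (
        table["q"] <= fdr_max
    )
    _LOG.info(
        "selected %d / %d genes (|fold| > %g, FDR <= %g)",
        int(table["selected"].sum()),
        len(table),
        fc_min,
        fdr_max,
    )
    return DEGeneSet(table=table, fc_min=fc_min, fdr_max=fdr_max)


# ----------------------------------------------------------------------
# file dialects


def load_expression(path: str | Path) -> pd.DataFrame:
    """Expression TSV: first column gene symbol, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df


def load_design(path: str | Path) -> pd.DataFrame:
    """Design TSV with columns sample, line, dye, array."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns:
        raise ValueError("design table needs a 'sample' column")
    return df.set_index("sample")
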