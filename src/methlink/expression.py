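"""Gene-count filtering, median-of-ratios normalization, and simple DE.

Counts are genes x samples.  Size factors follow the median-of-ratios scheme
(per-gene geometric mean across samples as the pseudo-reference; per-sample
factor = median ratio over genes positive everywhere).  Differential
expression fits, per gene, an ordinary linear model of log2(normalized + 1)
on the size-class indicator plus feed-stratum dummies and tests the group
coefficient with a two-sided t-test; raw p-values are BH-adjusted.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_genes",
    "size_factors",
    "normalize_counts",
    "differential_expression",
    "ma_volcano_tables",
]


def filter_genes(
    counts: pd.DataFrame,
    min_total: int = 10,
    min_count: int = 10,
    min_prevalence: float = 0.5,
    apply_total: bool = True,
    apply_prevalence: bool = True,
) -> pd.DataFrame:
    """Keep genes with total count >= min_total AND count >= min_count in at
    least a ``min_prevalence`` fraction of samples (each filter switchable)."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    keep = pd.Series(True, index=counts.index)
    if apply_total:
        keep &= counts.sum(axis=1) >= min_total
    if apply_prevalence:
        frac = (counts >= min_count).mean(axis=1)
        keep &= frac >= min_prevalence
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame, allow_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    The reference set is the genes with positive counts in every sample; each
    gene's pseudo-reference is its geometric mean across samples, and a
    sample's factor is the median of count/pseudo-reference over the set.
    With ``allow_pseudo_reference`` the geometric mean is taken over positive
    counts only (for sparse matrices with no everywhere-positive gene).
    """
    X = counts.to_numpy(dtype=float)
    positive = (X > 0).all(axis=1)
    if positive.any():
        ref = X[positive]
        log_geo = np.log(ref).mean(axis=1)
        ratios = ref / np.exp(log_geo)[:, None]
        factors = np.median(ratios, axis=0)
    elif allow_pseudo_reference:
        expressed = (X > 0).mean(axis=1) >= 0.5
        if not expressed.any():
            raise ValueError("no gene expressed in at least half the samples")
        ref = X[expressed]
        with np.errstate(divide="ignore"):
            logs = np.where(ref > 0, np.log(ref), np.nan)
        log_geo = np.nanmean(logs, axis=1)
        ratios = np.where(ref > 0, ref / np.exp(log_geo)[:, None], np.nan)
        factors = np.nanmedian(ratios, axis=0)
    else:
        raise ValueError(
            "no gene has positive counts in all samples; "
            "set allow_pseudo_reference=True to use a positive-count fallback"
        )
    if (factors <= 0).any() or np.isnan(factors).any():
        raise ValueError("degenerate size factors; check the count matrix")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Counts divided by their sample's size factor."""
    return counts / factors.reindex(counts.columns)


def _design_matrix(
    group: np.ndarray, strata: np.ndarray, reference: str
) -> tuple[np.ndarray, np.ndarray]:
    """(design, sample mask) after dropping strata with an empty group cell.

    Columns: intercept, non-reference indicator, then stratum dummies
    (first retained stratum as baseline).
    """
    keep = np.ones(len(group), dtype=bool)
    strata_levels = []
    for s in np.unique(strata):
        idx = strata == s
        cells = np.unique(group[idx])
        if len(cells) < 2:
            warnings.warn(f"stratum {s!r} lacks a group cell; dropped")
            keep[idx] = False
        else:
            strata_levels.append(s)
    if not strata_levels:
        raise ValueError("no stratum retains both groups")
    g = group[keep]
    st = strata[keep]
    n = keep.sum()
    cols = [np.ones(n), (g != reference).astype(float)]
    for s in strata_levels[1:]:
        cols.append((st == s).astype(float))
    return np.column_stack(cols), keep


def differential_expression(
    counts: pd.DataFrame,
    factors: pd.Series,
    group_labels: Sequence,
    strata_labels: Sequence,
    reference: str,
) -> pd.DataFrame:
    """Per-gene linear-model test of the size-class effect on log2 expression.

    Response: log2(count/size_factor + 1).  LFC is the group coefficient
    (positive = higher in the non-reference group).  Returns a frame with
    lfc, t, p, q (BH) indexed by gene.
    """
    group = np.asarray(group_labels)
    strata = np.asarray(strata_labels)
    uniq = set(np.unique(group))
    if reference not in uniq or len(uniq) != 2:
        raise ValueError("need exactly two groups including the reference")
    X, keep = _design_matrix(group, strata, reference)
    norm = normalize_counts(counts, factors).to_numpy()[:, keep]
    Y = np.log2(norm + 1.0).T  # samples x genes

    n, k = X.shape
    df = n - k
    if df <= 0:
        raise ValueError("not enough samples for the design")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y  # k x genes
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2, 0) * XtX_inv[1, 1])
    lfc = beta[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    p = 2 * stats.t.sf(np.abs(t), df)
    # constant genes: zero coefficient with zero residual variance -> no
    # evidence either way; report p = 1
    degenerate = se < 1e-12
    null_effect = np.abs(lfc) < 1e-10
    p = np.where(degenerate & null_effect, 1.0, p)
    t = np.where(degenerate & null_effect, 0.0, t)
    lfc = np.where(degenerate & null_effect, 0.0, lfc)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"lfc": lfc, "t": t, "p": p, "q": q}, index=counts.index
    )


def ma_volcano_tables(
    de_result: pd.DataFrame, normalized: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MA table (A = log2(mean normalized + 1), M = LFC) and volcano table
    (LFC, -log10 p)."""
    a = np.log2(normalized.mean(axis=1) + 1.0)
    ma = pd.DataFrame({"A": a.reindex(de_result.index), "M": de_result["lfc"]})
    volcano = pd.DataFrame(
        {"lfc": de_result["lfc"], "neg_log10_p": -np.log10(de_result["p"])}
    )
    return ma, volcano
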