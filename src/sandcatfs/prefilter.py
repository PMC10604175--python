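"""Differential-expression prefilter for the gene space.

Wrapper optimization over thousands of genes is hopeless; the pipeline
first shrinks the search space to genes that differ between the two
classes.  The gate here is a Welch two-sample t-test per gene on the
(assumed log-scale) expression, Benjamini–Hochberg adjustment across
genes, and a threshold at adjusted p < alpha with an optional
|log2 fold-change| floor.  On log-scale data the log2 fold-change is
simply the difference of group means.  The optimizer downstream is
agnostic to which differential-expression gate produced its input.

Also provides per-gene z-score standardization (sample mean 0, sample
standard deviation 1, ddof = 1), with zero-variance genes zeroed out and
flagged rather than raising.

The `DifferentialExpressionFilter` estimator wraps the same computation
as a scikit-learn feature selector so it can sit in a Pipeline ahead of
the swarm selectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y
from statsmodels.stats.multitest import multipletests

from .io import LabeledExpression

__all__ = [
    "DETable",
    "zscore_normalize",
    "differential_expression",
    "filter_degs",
    "DifferentialExpressionFilter",
]


@dataclass
class DETable:
    """Per-gene differential-expression statistics."""

    gene_ids: list[str]
    mean_diff: np.ndarray
    logfc: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    adj_p: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "mean_diff": self.mean_diff,
                "logfc": self.logfc,
                "t_stat": self.t_stat,
                "p_value": self.p_value,
                "adj_p": self.adj_p,
            }
        )


def zscore_values(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize columns to mean 0, sd 1 (ddof=1).

    Returns ``(Z, zero_variance_flags)``; zero-variance columns become
    all-zero and are flagged instead of raising.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    flags = sd == 0.0
    safe_sd = np.where(flags, 1.0, sd)
    Z = (X - mu) / safe_sd
    Z[:, flags] = 0.0
    return Z, flags


def zscore_normalize(data: LabeledExpression) -> LabeledExpression:
    """Per-gene z-score standardization of a labeled matrix."""
    Z, flags = zscore_values(data.values)
    if flags.any():
        warnings.warn(
            f"{int(flags.sum())} zero-variance gene(s) set to all-zero", stacklevel=2
        )
    return LabeledExpression(
        values=Z,
        sample_ids=list(data.sample_ids),
        gene_ids=list(data.gene_ids),
        labels=list(data.labels),
        zero_variance_flags=flags,
    )


def de_statistics(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Welch t, two-sided p, BH-adjusted p and mean difference per column.

    ``y`` must hold exactly two classes with >= 2 samples each.  The
    mean difference (class 1 minus class 0) doubles as the log2
    fold-change on log-scale expression.  Zero-variance-in-both-groups
    genes get t = 0, p = 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"two classes required, found {len(classes)}")
    g0 = X[y == classes[0]]
    g1 = X[y == classes[1]]
    if g0.shape[0] < 2 or g1.shape[0] < 2:
        raise ValueError("each class needs at least 2 samples for a Welch t-test")
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p_value = stats.ttest_ind(g1, g0, axis=0, equal_var=False)
    t_stat = np.asarray(t_stat, dtype=float)
    p_value = np.asarray(p_value, dtype=float)
    degenerate = ~np.isfinite(t_stat)
    t_stat[degenerate] = 0.0
    p_value[degenerate] = 1.0
    _, adj_p, _, _ = multipletests(p_value, method="fdr_bh")
    mean_diff = g1.mean(axis=0) - g0.mean(axis=0)
    return t_stat, p_value, adj_p, mean_diff


def differential_expression(data: LabeledExpression) -> DETable:
    """Per-gene Welch t-test with BH adjustment on a labeled matrix."""
    t_stat, p_value, adj_p, mean_diff = de_statistics(data.values, data.y)
    return DETable(
        gene_ids=list(data.gene_ids),
        mean_diff=mean_diff,
        logfc=mean_diff,  # difference of group means on log-scale data
        t_stat=t_stat,
        p_value=p_value,
        adj_p=adj_p,
    )


def filter_degs(
    table: DETable, alpha: float = 0.05, logfc_min: float | None = None
) -> np.ndarray:
    """Indices of genes passing adj_p < alpha (and |logfc| > logfc_min).

    Original gene order is preserved.  An empty result warns rather than
    raising; the caller decides whether to proceed unfiltered.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    keep = table.adj_p < alpha
    if logfc_min is not None:
        keep &= np.abs(table.logfc) > logfc_min
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        warnings.warn(
            f"no genes pass adj_p < {alpha}"
            + (f" with |logFC| > {logfc_min}" if logfc_min is not None else ""),
            stacklevel=2,
        )
    return idx


class DifferentialExpressionFilter(SelectorMixin, BaseEstimator):
    """scikit-learn selector keeping genes differential between two classes.

    Parameters
    ----------
    alpha : float, default 0.05
        Benjamini–Hochberg adjusted-p threshold (strict ``<``).
    logfc_min : float or None, default None
        Optional absolute log2 fold-change floor (strict ``>``); on
        log-scale data logFC is the difference of group means.
    keep_all_if_empty : bool, default False
        If no gene passes, keep every gene (with a warning) instead of
        selecting none.

    Attributes
    ----------
    support_ : bool ndarray of shape (n_features,)
        Mask of retained genes.
    de_table_ : pandas.DataFrame
        Per-gene t statistic, p, adjusted p and logFC.
    """

    def __init__(self, alpha: float = 0.05, logfc_min: float | None = None,
                 keep_all_if_empty: bool = False):
        self.alpha = alpha
        self.logfc_min = logfc_min
        self.keep_all_if_empty = keep_all_if_empty

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        t_stat, p_value, adj_p, mean_diff = de_statistics(X, y)
        table = DETable(
            gene_ids=[f"g{j}" for j in range(X.shape[1])],
            mean_diff=mean_diff, logfc=mean_diff,
            t_stat=t_stat, p_value=p_value, adj_p=adj_p,
        )
        idx = filter_degs(table, alpha=self.alpha, logfc_min=self.logfc_min)
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[idx] = True
        if not mask.any() and self.keep_all_if_empty:
            mask[:] = True
        self.support_ = mask
        self.de_table_ = table.to_frame()
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
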