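"""Aligned count-regression data: response counts, design matrix, tip labels."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import PhyloCovariance, PhyloTree, tree_to_covariance

logger = logging.getLogger(__name__)

__all__ = ["CountRegData", "align_data"]


@dataclass
class CountRegData:
    """Response counts Y and design matrix X, row-aligned by tip label.

    The first column of X is the all-ones intercept column; the remaining
    columns are the covariates, named in ``colnames`` (intercept included).
    """

    labels: list[str]
    y: np.ndarray
    X: np.ndarray
    colnames: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = len(self.labels)
        if self.y.shape != (n,):
            raise ValueError(f"Y has shape {self.y.shape}, expected ({n},)")
        if self.X.shape[0] != n:
            raise ValueError(
                f"X has {self.X.shape[0]} rows for {n} labels"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("design matrix contains non-finite values")
        yf = np.asarray(self.y, dtype=float)
        if np.any(yf < 0) or np.any(yf != np.round(yf)):
            bad = [self.labels[i] for i in np.nonzero((yf < 0) | (yf != np.round(yf)))[0]]
            raise ValueError(f"response must be nonnegative integers; offending rows: {bad}")
        self.y = yf.astype(np.int64)
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first column of X must be the intercept (all ones)")
        if not self.colnames:
            self.colnames = ["intercept"] + [f"x{j}" for j in range(1, self.X.shape[1])]
        if len(self.colnames) != self.X.shape[1]:
            raise ValueError("colnames length does not match X columns")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def p(self) -> int:
        """Number of covariates (X has p+1 columns)."""
        return self.X.shape[1] - 1

    @classmethod
    def from_arrays(cls, y, x, labels=None, colnames=None) -> "CountRegData":
        """Build from a response vector and covariate array (intercept added)."""
        y = np.asarray(y)
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        n = len(y)
        if labels is None:
            labels = [f"t{i + 1}" for i in range(n)]
        X = np.column_stack([np.ones(n), x])
        if colnames is None:
            colnames = ["intercept"] + [f"x{j}" for j in range(1, X.shape[1])]
        return cls(list(labels), y, X, list(colnames))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str, covariates) -> "CountRegData":
        """Build from a species-by-trait table indexed by tip label.

        Rows with missing response/covariate values are dropped (listwise
        deletion) with a log message naming the species.
        """
        covariates = list(covariates)
        cols = [response] + covariates
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise KeyError(f"columns not in table: {missing}")
        sub = df[cols]
        incomplete = sub.index[sub.isna().any(axis=1)].tolist()
        if incomplete:
            logger.warning("dropping %d species with missing values: %s",
                           len(incomplete), incomplete)
            sub = sub.dropna()
        labels = [str(l) for l in sub.index]
        return cls.from_arrays(
            sub[response].to_numpy(),
            sub[covariates].to_numpy(dtype=float),
            labels=labels,
            colnames=["intercept"] + covariates,
        )


def align_data(
    tree: PhyloTree,
    table: pd.DataFrame,
    response: str,
    covariates,
) -> tuple[CountRegData, PhyloCovariance]:
    """Intersect tree tips with table rows and return jointly ordered data and C.

    The canonical order is the trait table's row order (restricted to shared
    labels); the covariance matrix is permuted to match, preventing silent
    misalignment.  Labels present on only one side are dropped with a log
    message.
    """
    data_all = CountRegData.from_dataframe(table, response, covariates)
    tips = set(tree.tip_labels)
    table_labels = data_all.labels
    shared = [l for l in table_labels if l in tips]
    dropped_rows = [l for l in table_labels if l not in tips]
    dropped_tips = sorted(tips - set(table_labels))
    if dropped_rows:
        logger.warning("table rows without matching tips dropped: %s", dropped_rows)
    if dropped_tips:
        logger.warning("tree tips without table rows ignored: %s", dropped_tips)
    if len(shared) < 2:
        raise ValueError(
            "fewer than 2 labels shared between tree and table "
            f"(tree tips: {sorted(tips)[:5]}..., table rows: {table_labels[:5]}...)"
        )
    keep = [table_labels.index(l) for l in shared]
    data = CountRegData(
        shared,
        data_all.y[keep],
        data_all.X[keep],
        data_all.colnames,
    )
    C = tree_to_covariance(tree).reorder(shared)
    return data, C
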