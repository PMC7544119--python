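"""Rank-percentile transformation.

Each sample's expression vector is mapped, independently of every other
sample, onto [0, 1] by rank: the most highly expressed gene receives 1, the
lowest 0, and intermediate genes are uniformly spaced by rank.  Tied values
share the average of their would-be ranks.  With 1-based average ranks over
G genes the percentile is ``(avg_rank - 1) / (G - 1)``; an all-tied sample
therefore maps to 0.5 everywhere.

Because the transform is per-sample, adding new samples never requires
renormalising existing ones — the property that makes the atlas scalable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datamodel import ExpressionMatrix

__all__ = ["rank_percentile", "rank_percentile_single", "rank_percentile_frame", "RankPercentile"]


def rank_percentile_single(values, universe_size: int | None = None) -> np.ndarray:
    """Rank-percentile transform of a single sample's expression vector.

    Parameters
    ----------
    values : array-like of shape (n_genes,)
        Raw expression values for one sample.
    universe_size : int, optional
        Size of the gene universe the ranks are scaled over.  Defaults to
        ``len(values)``; must be at least ``len(values)``.  Used by
        projection, where genes absent from a sample are later assigned
        percentile 0 (the lowest rank).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if x.size < 2:
        raise ValueError("rank transform requires at least 2 genes")
    if not np.all(np.isfinite(x)):
        raise ValueError("rank transform requires finite values")
    g = x.size if universe_size is None else int(universe_size)
    if g < x.size:
        raise ValueError(f"universe_size ({g}) smaller than vector length ({x.size})")
    ranks = rankdata(x, method="average")  # 1-based, ties averaged
    return (ranks - 1.0) / (g - 1.0)


def rank_percentile_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Column-wise (per-sample) rank-percentile transform of a genes x samples frame."""
    arr = frame.to_numpy(dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("rank transform requires at least 2 genes")
    if not np.all(np.isfinite(arr)):
        raise ValueError("rank transform requires finite values")
    ranks = rankdata(arr, method="average", axis=0)
    out = (ranks - 1.0) / (arr.shape[0] - 1.0)
    return pd.DataFrame(out, index=frame.index, columns=frame.columns)


def rank_percentile(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Transform a raw :class:`ExpressionMatrix` into rank percentiles."""
    if expr.value_kind != "raw":
        raise ValueError("input is already rank-transformed")
    return ExpressionMatrix(rank_percentile_frame(expr.values), value_kind="percentile")


class RankPercentile(BaseEstimator, TransformerMixin):
    """Stateless scikit-learn transformer applying the rank-percentile map.

    Operates on samples x genes arrays (scikit-learn orientation); each row
    is transformed independently.  ``fit`` only records the number of
    features.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x genes)")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count changed between fit and transform")
        if X.shape[1] < 2:
            raise ValueError("rank transform requires at least 2 genes")
        if not np.all(np.isfinite(X)):
            raise ValueError("rank transform requires finite values")
        ranks = rankdata(X, method="average", axis=1)
        return (ranks - 1.0) / (X.shape[1] - 1.0)
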