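"""Scikit-learn style normalizers for RT-PCR CT matrices.

All estimators follow the sklearn convention: ``X`` has shape
``(n_samples, n_genes)`` with NaN marking missing (undetected) wells
where a method tolerates them.  The pseudo-control family
(:class:`MeanCT0`, :class:`TopKCT0`, :class:`WeightedMeanCT0`,
:class:`RankInvariantCT0`) learns per-gene state (stability weights, a
selected gene set) in ``fit`` and, in ``transform``, subtracts a
per-sample pseudo-control CT0 computed from the sample's own CT values,
yielding dCT = CT - CT0.  The full-matrix family
(:class:`QuantileNormalizer`, :class:`MedianShiftNormalizer`,
:class:`CyclicLoessNormalizer`) returns adjusted CT values instead.

The weighted-mean pseudo-control weights gene *j* by

    w_j = (1 / max(sd_j, eps))**wmp / sum_i (1 / max(sd_i, eps))**wmp

where sd_j is the gene's across-sample standard deviation and *wmp*
(the weighted-mean power) interpolates between the plain mean of all
genes (wmp = 0) and the single most stable gene (wmp large).  CT0 is
then the convex combination sum_j w_j CT_j within each sample.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "MeanCT0",
    "TopKCT0",
    "WeightedMeanCT0",
    "RankInvariantCT0",
    "QuantileNormalizer",
    "MedianShiftNormalizer",
    "CyclicLoessNormalizer",
    "nan_gene_sd",
]


def _as_array(X, *, allow_nan: bool = True) -> tuple[np.ndarray, np.ndarray | None]:
    """Coerce to a 2-D float array; return (values, feature names or None)."""
    names = None
    if isinstance(X, pd.DataFrame):
        names = np.asarray(X.columns, dtype=object)
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D samples x genes matrix, got ndim={X.ndim}")
    if np.isinf(X).any():
        raise ValueError("CT values must be finite or NaN")
    if not allow_nan and np.isnan(X).any():
        raise ValueError(
            "missing values are not supported by this method; apply "
            "filter_genes (drop_any_missing) first")
    return X, names


def nan_gene_sd(X: np.ndarray) -> np.ndarray:
    """Per-gene (per-column) sample standard deviation, ddof=1, over
    observed entries; NaN for genes with fewer than 2 observations."""
    X = np.asarray(X, dtype=float)
    n_obs = np.sum(~np.isnan(X), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(X, axis=0, ddof=1)
    sd = np.where(n_obs >= 2, sd, np.nan)
    return sd


class _CT0Mixin(TransformerMixin, BaseEstimator):
    """Shared dCT machinery: ``transform`` subtracts the per-sample CT0."""

    def ct0(self, X) -> np.ndarray:
        """Per-sample pseudo-control CT values for ``X``."""
        check_is_fitted(self)
        Xv, _ = _as_array(X)
        if Xv.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {Xv.shape[1]} genes, expected {self.n_features_in_}")
        return self._ct0(Xv)

    def transform(self, X):
        Xv, _ = _as_array(X)
        out = Xv - self.ct0(Xv)[:, None]
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out

    def _more_tags(self):
        return {"allow_nan": True}


class MeanCT0(_CT0Mixin):
    """Plain per-sample statistic as the pseudo-control.

    Parameters
    ----------
    kind : {"arithmetic", "geometric", "median"}
        Statistic taken over each sample's observed CT values.  The
        geometric mean is computed on the CT scale itself.
    """

    def __init__(self, kind: str = "arithmetic"):
        self.kind = kind

    def fit(self, X, y=None):
        Xv, names = _as_array(X)
        if self.kind not in {"arithmetic", "geometric", "median"}:
            raise ValueError(f"unknown kind {self.kind!r}")
        self.n_features_in_ = Xv.shape[1]
        if names is not None:
            self.feature_names_in_ = names
        return self

    def _ct0(self, Xv: np.ndarray) -> np.ndarray:
        empty = np.all(np.isnan(Xv), axis=1)
        if empty.any():
            raise ValueError(
                f"samples with no observed CT values: {np.where(empty)[0].tolist()}")
        if self.kind == "arithmetic":
            return np.nanmean(Xv, axis=1)
        if self.kind == "median":
            return np.nanmedian(Xv, axis=1)
        return np.exp(np.nanmean(np.log(Xv), axis=1))


class TopKCT0(_CT0Mixin):
    """Mean of the k most stable genes as the pseudo-control.

    Stability is across-sample standard deviation, learned in ``fit``;
    the same k genes (lowest sd, ties broken by gene name then column
    order) are averaged within every sample.
    """

    def __init__(self, k: int = 8):
        self.k = k

    def fit(self, X, y=None):
        Xv, names = _as_array(X)
        if not (isinstance(self.k, (int, np.integer)) and self.k >= 1):
            raise ValueError("k must be a positive integer")
        sd = nan_gene_sd(Xv)
        eligible = ~np.isnan(sd)
        if self.k > eligible.sum():
            raise ValueError(
                f"k={self.k} exceeds the {int(eligible.sum())} genes with a "
                "defined standard deviation")
        idx = np.arange(Xv.shape[1])
        tie_key = names.astype(str) if names is not None else idx.astype(str)
        order = (
            pd.DataFrame({"sd": np.where(eligible, sd, np.inf), "name": tie_key})
            .sort_values(["sd", "name"], kind="mergesort")
            .index.to_numpy()
        )
        self.gene_sd_ = sd
        self.selected_idx_ = np.sort(order[: self.k])
        if names is not None:
            self.feature_names_in_ = names
            self.selected_features_ = names[self.selected_idx_]
        self.n_features_in_ = Xv.shape[1]
        return self

    def _ct0(self, Xv: np.ndarray) -> np.ndarray:
        sub = Xv[:, self.selected_idx_]
        empty = np.all(np.isnan(sub), axis=1)
        if empty.any():
            raise ValueError(
                "samples with no observed CT among the selected genes: "
                f"{np.where(empty)[0].tolist()}")
        return np.nanmean(sub, axis=1)


class WeightedMeanCT0(_CT0Mixin):
    """Stability-weighted mean of all genes as the pseudo-control.

    Parameters
    ----------
    wmp : float >= 0
        Weighted-mean power.  0 gives the plain arithmetic mean; large
        values converge on the single most stable gene.
    epsilon : float > 0
        Floor (cycles) applied to per-gene standard deviations so a
        zero-variance gene cannot receive infinite weight.
    """

    def __init__(self, wmp: float = 1.0, epsilon: float = 0.01):
        self.wmp = wmp
        self.epsilon = epsilon

    def fit(self, X, y=None):
        Xv, names = _as_array(X)
        if not np.isfinite(self.wmp) or self.wmp < 0:
            raise ValueError("wmp must be a nonnegative real")
        if not np.isfinite(self.epsilon) or self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        sd = nan_gene_sd(Xv)
        eligible = ~np.isnan(sd)
        if not eligible.any():
            raise ValueError("no gene has a defined standard deviation")
        floored = np.maximum(sd, self.epsilon)
        # log-scale power for numerical stability at large wmp; the raw
        # weights are scaled so the most stable gene has weight exactly 1,
        # which makes wmp=0 collapse to the arithmetic mean bitwise
        logw = np.where(eligible, -self.wmp * np.log(floored), -np.inf)
        logw -= np.nanmax(logw[eligible])
        w = np.exp(logw)
        w[~eligible] = 0.0
        self.gene_sd_ = sd
        self._raw_weights_ = w
        self.weights_ = w / w.sum()
        if names is not None:
            self.feature_names_in_ = names
        self.n_features_in_ = Xv.shape[1]
        return self

    def _ct0(self, Xv: np.ndarray) -> np.ndarray:
        W = np.where(np.isnan(Xv), 0.0, self._raw_weights_[None, :])
        denom = W.sum(axis=1)
        if np.any(denom <= 0):
            raise ValueError(
                "samples with no observed CT among weighted genes: "
                f"{np.where(denom <= 0)[0].tolist()}")
        num = np.nansum(Xv * W, axis=1)
        return num / denom


class RankInvariantCT0(_CT0Mixin):
    """Mean CT of the rank-invariant gene set as the pseudo-control.

    A gene is rank-invariant when its within-sample rank differs from
    its rank in the reference sample by at most ``rank_window`` in every
    sample.  The reference defaults to the sample whose mean CT is the
    median of the sample means.
    """

    def __init__(self, reference: str | int = "median_sample",
                 rank_window: int | None = None):
        self.reference = reference
        self.rank_window = rank_window

    def fit(self, X, y=None):
        Xv, names = _as_array(X)
        n_samples, n_genes = Xv.shape
        if n_samples < 2:
            raise ValueError("rank-invariant selection needs >= 2 samples")
        window = self.rank_window
        if window is None:
            window = int(np.ceil(0.05 * n_genes))
        if window < 0:
            raise ValueError("rank_window must be nonnegative")

        complete = ~np.isnan(Xv).any(axis=0)
        if self.reference == "median_sample":
            means = np.nanmean(Xv, axis=1)
            ref_idx = int(np.argsort(means, kind="stable")[(n_samples - 1) // 2])
        elif isinstance(self.reference, (int, np.integer)):
            ref_idx = int(self.reference)
        else:
            raise ValueError(
                "reference must be 'median_sample' or a sample index")

        sub = Xv[:, complete]
        ranks = np.apply_along_axis(rankdata, 1, sub)
        invariant_sub = np.all(
            np.abs(ranks - ranks[ref_idx]) <= window, axis=0)
        invariant = np.zeros(n_genes, dtype=bool)
        invariant[np.where(complete)[0][invariant_sub]] = True
        if not invariant.any():
            raise ValueError(
                "no rank-invariant genes found; increase rank_window")
        self.reference_idx_ = ref_idx
        self.rank_window_ = window
        self.invariant_mask_ = invariant
        self.invariant_idx_ = np.where(invariant)[0]
        if names is not None:
            self.feature_names_in_ = names
            self.invariant_features_ = names[invariant]
        self.n_features_in_ = n_genes
        return self

    def _ct0(self, Xv: np.ndarray) -> np.ndarray:
        return np.nanmean(Xv[:, self.invariant_idx_], axis=1)


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Force every sample's CT distribution onto a shared reference.

    The reference distribution is the per-rank mean (or median) of the
    sorted training samples; ``transform`` replaces each sample's values
    by the reference value at the corresponding rank, preserving the
    within-sample ordering.  Ties receive the mean of the reference
    values they span (midrank convention).  Requires complete matrices.
    """

    def __init__(self, center: str = "mean"):
        self.center = center

    def fit(self, X, y=None):
        Xv, names = _as_array(X, allow_nan=False)
        if self.center not in {"mean", "median"}:
            raise ValueError(f"unknown center {self.center!r}")
        stat = np.mean if self.center == "mean" else np.median
        self.reference_distribution_ = stat(np.sort(Xv, axis=1), axis=0)
        if names is not None:
            self.feature_names_in_ = names
        self.n_features_in_ = Xv.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        Xv, _ = _as_array(X, allow_nan=False)
        if Xv.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {Xv.shape[1]} genes, expected {self.n_features_in_}")
        ref = self.reference_distribution_
        out = np.empty_like(Xv)
        for i, row in enumerate(Xv):
            order = np.argsort(row, kind="mergesort")
            mapped = np.empty_like(ref)
            mapped[order] = ref
            # midrank: average the reference values spanned by each tie group
            grouped = pd.Series(mapped).groupby(pd.Series(row)).transform("mean")
            out[i] = grouped.to_numpy()
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


class MedianShiftNormalizer(TransformerMixin, BaseEstimator):
    """Shift each sample by a constant so all medians agree.

    The target is the median of the per-sample medians of the training
    data; within-sample differences are untouched.
    """

    def fit(self, X, y=None):
        Xv, names = _as_array(X)
        empty = np.all(np.isnan(Xv), axis=1)
        if empty.any():
            raise ValueError(
                f"samples with no observed CT values: {np.where(empty)[0].tolist()}")
        self.target_median_ = float(np.median(np.nanmedian(Xv, axis=1)))
        if names is not None:
            self.feature_names_in_ = names
        self.n_features_in_ = Xv.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        Xv, _ = _as_array(X)
        shifts = self.target_median_ - np.nanmedian(Xv, axis=1)
        out = Xv + shifts[:, None]
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out

    def _more_tags(self):
        return {"allow_nan": True}


class CyclicLoessNormalizer(TransformerMixin, BaseEstimator):
    """Pairwise MA-style loess normalization of log CT values.

    For each unordered sample pair, M = log CT1 - log CT2 and
    A = (log CT1 + log CT2)/2; a lowess fit F of M on A is split evenly
    between the two samples (log CT1 -= F/2, log CT2 += F/2).  All pairs
    are cycled until the largest mean |F| falls below ``tol`` or
    ``max_cycles`` is reached; the result is back-transformed from log
    scale.  This operates jointly on the whole matrix, so ``transform``
    re-runs the procedure on the matrix it is given.
    """

    def __init__(self, span: float = 0.7, max_cycles: int = 3, tol: float = 0.01):
        self.span = span
        self.max_cycles = max_cycles
        self.tol = tol

    def fit(self, X, y=None):
        Xv, names = _as_array(X, allow_nan=False)
        if not 0 < self.span <= 1:
            raise ValueError("span must lie in (0, 1]")
        if Xv.shape[0] < 2:
            raise ValueError("cyclic loess needs >= 2 samples")
        if names is not None:
            self.feature_names_in_ = names
        self.n_features_in_ = Xv.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        Xv, _ = _as_array(X, allow_nan=False)
        L = np.log(Xv)
        n_samples = L.shape[0]
        converged = False
        n_cycles = 0
        for _ in range(self.max_cycles):
            n_cycles += 1
            worst = 0.0
            for i in range(n_samples - 1):
                for j in range(i + 1, n_samples):
                    M = L[i] - L[j]
                    A = 0.5 * (L[i] + L[j])
                    F = lowess(M, A, frac=self.span, return_sorted=False)
                    L[i] -= F / 2.0
                    L[j] += F / 2.0
                    worst = max(worst, float(np.mean(np.abs(F))))
            if worst < self.tol:
                converged = True
                break
        self.n_cycles_ = n_cycles
        self.converged_ = converged
        out = np.exp(L)
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out
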