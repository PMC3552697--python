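"""Pseudo-control construction, full-matrix normalization and the
dCT / ddCT / fold-change calculus, as functions over :class:`CTMatrix`.

Each function is a thin wrapper over the corresponding estimator in
:mod:`ctnorm.estimators`, fitted and applied on the same matrix, with
method and parameters recorded as provenance on the result.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .core import CTMatrix, CT0Vector, NormalizedMatrix
from . import estimators as est

__all__ = [
    "WeightedMeanParams",
    "FoldChangeResult",
    "gene_sd",
    "mean_ct0",
    "topk_ct0",
    "weighted_mean_ct0",
    "rank_invariant_ct0",
    "delta_ct",
    "delta_delta_ct_fold_change",
    "quantile_normalize",
    "median_normalize",
    "cyclic_loess_normalize",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class WeightedMeanParams:
    """Parameters of the weighted-mean pseudo-control.

    wmp: weighted-mean power (>= 0); 0 is the plain mean, large values
    approach the single most stable gene.  epsilon: positive floor on
    per-gene standard deviations, in cycles.
    """

    wmp: float = 1.0
    epsilon: float = 0.01

    def __post_init__(self):
        if not np.isfinite(self.wmp) or self.wmp < 0:
            raise ValueError("wmp must be a nonnegative real")
        if not np.isfinite(self.epsilon) or self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclasses.dataclass
class FoldChangeResult:
    """Per-gene ddCT and the implied fold change 2**(-ddCT)."""

    gene_ids: list[str]
    delta_delta_ct: np.ndarray
    fold_change: np.ndarray


def _samples_by_genes(matrix: CTMatrix) -> pd.DataFrame:
    return matrix.data.T


def gene_sd(matrix: CTMatrix) -> pd.Series:
    """Across-sample sample standard deviation (ddof=1) per gene.

    Genes with fewer than 2 observed wells are omitted from the result
    (and logged), since their standard deviation is undefined.
    """
    sd = est.nan_gene_sd(_samples_by_genes(matrix).to_numpy())
    out = pd.Series(sd, index=matrix.data.index, name="sd")
    omitted = out.index[out.isna()].tolist()
    if omitted:
        logger.info("genes omitted from sd (fewer than 2 observed wells): %s",
                    omitted)
    return out.dropna()


def mean_ct0(matrix: CTMatrix, kind: str = "arithmetic") -> CT0Vector:
    """Plain per-sample mean / median / geometric-mean pseudo-control."""
    model = est.MeanCT0(kind=kind).fit(_samples_by_genes(matrix))
    vals = model.ct0(_samples_by_genes(matrix))
    return CT0Vector(pd.Series(vals, index=matrix.data.columns),
                     method=f"mean:{kind}", params={"kind": kind})


def topk_ct0(matrix: CTMatrix, k: int) -> CT0Vector:
    """Mean of the k genes with smallest across-sample sd, per sample."""
    X = _samples_by_genes(matrix)
    model = est.TopKCT0(k=k).fit(X)
    vals = model.ct0(X)
    return CT0Vector(
        pd.Series(vals, index=matrix.data.columns),
        method="topk",
        params={"k": k, "selected_genes": list(model.selected_features_)},
    )


def weighted_mean_ct0(
    matrix: CTMatrix,
    params: WeightedMeanParams | None = None,
    *,
    wmp: float | None = None,
    epsilon: float | None = None,
) -> CT0Vector:
    """Stability-weighted mean pseudo-control (weights sum to 1 per sample)."""
    if params is None:
        params = WeightedMeanParams(
            wmp=1.0 if wmp is None else wmp,
            epsilon=0.01 if epsilon is None else epsilon)
    X = _samples_by_genes(matrix)
    model = est.WeightedMeanCT0(wmp=params.wmp, epsilon=params.epsilon).fit(X)
    vals = model.ct0(X)
    return CT0Vector(
        pd.Series(vals, index=matrix.data.columns),
        method="weighted",
        params={"wmp": params.wmp, "epsilon": params.epsilon},
    )


def rank_invariant_ct0(
    matrix: CTMatrix,
    reference: str = "median_sample",
    rank_window: int | None = None,
) -> CT0Vector:
    """Mean CT of the genes rank-invariant against a reference sample."""
    X = _samples_by_genes(matrix)
    if reference != "median_sample":
        if reference not in matrix.data.columns:
            raise ValueError(f"unknown reference sample {reference!r}")
        reference_arg = list(matrix.data.columns).index(reference)
    else:
        reference_arg = "median_sample"
    model = est.RankInvariantCT0(
        reference=reference_arg, rank_window=rank_window).fit(X)
    vals = model.ct0(X)
    return CT0Vector(
        pd.Series(vals, index=matrix.data.columns),
        method="rankinv",
        params={
            "reference": matrix.data.columns[model.reference_idx_],
            "rank_window": model.rank_window_,
            "invariant_genes": list(model.invariant_features_),
        },
    )


def delta_ct(matrix: CTMatrix, ct0: CT0Vector) -> NormalizedMatrix:
    """dCT = CT - CT0 of the well's sample; missing wells stay missing."""
    if list(ct0.values.index) != list(matrix.data.columns):
        raise ValueError("CT0 sample ids do not match the matrix sample ids")
    data = matrix.data.sub(ct0.values, axis=1)
    return NormalizedMatrix(data, method=ct0.method, scale="delta_ct",
                            params=dict(ct0.params))


def delta_delta_ct_fold_change(
    experimental: pd.Series, control: pd.Series
) -> FoldChangeResult:
    """ddCT = dCT(experimental) - dCT(control); FC = 2**(-ddCT).

    Both inputs are per-gene dCT vectors indexed by gene id; the gene
    sets must match exactly.
    """
    if set(experimental.index) != set(control.index):
        extra = set(experimental.index) ^ set(control.index)
        raise ValueError(f"unmatched gene ids between conditions: {sorted(extra)}")
    control = control.reindex(experimental.index)
    ddct = (experimental - control).to_numpy(dtype=float)
    return FoldChangeResult(
        gene_ids=list(experimental.index),
        delta_delta_ct=ddct,
        fold_change=np.exp2(-ddct),
    )


def quantile_normalize(matrix: CTMatrix, center: str = "mean") -> NormalizedMatrix:
    """Quantile normalization: identical sorted CT multiset in every sample."""
    X = _samples_by_genes(matrix)
    if X.isna().to_numpy().any():
        raise ValueError(
            "quantile normalization requires a complete matrix; apply "
            "filter_genes first")
    out = est.QuantileNormalizer(center=center).fit(X).transform(X)
    return NormalizedMatrix(out.T, method=f"quantile:{center}",
                            scale="adjusted_ct", params={"center": center})


def median_normalize(matrix: CTMatrix) -> NormalizedMatrix:
    """Shift each sample so all per-sample medians coincide."""
    X = _samples_by_genes(matrix)
    model = est.MedianShiftNormalizer().fit(X)
    out = model.transform(X)
    return NormalizedMatrix(out.T, method="medianshift", scale="adjusted_ct",
                            params={"target_median": model.target_median_})


def cyclic_loess_normalize(
    matrix: CTMatrix,
    span: float = 0.7,
    max_cycles: int = 3,
    tol: float = 0.01,
) -> NormalizedMatrix:
    """Pairwise MA loess normalization on log CT (see CyclicLoessNormalizer)."""
    X = _samples_by_genes(matrix)
    if X.isna().to_numpy().any():
        raise ValueError(
            "cyclic loess requires a complete matrix; apply filter_genes first")
    model = est.CyclicLoessNormalizer(
        span=span, max_cycles=max_cycles, tol=tol).fit(X)
    out = model.transform(X)
    if not model.converged_:
        logger.warning("cyclic loess did not converge within %d cycles",
                       max_cycles)
    return NormalizedMatrix(
        out.T, method="loess", scale="adjusted_ct",
        params={"span": span, "max_cycles": max_cycles, "tol": tol,
                "n_cycles": model.n_cycles_, "converged": model.converged_})
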