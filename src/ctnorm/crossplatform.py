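"""Concordance between RT-PCR dCT values and microarray log2 intensity.

Because CT is inversely and logarithmically related to abundance, dCT
should correlate *negatively* with log2 microarray intensity for the
same genes.  Concordance is measured with Spearman's rank correlation,
overall and within bins of mean raw CT (abundance strata), since the
CT-dependent bias may erode agreement for low-abundance genes.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import CTMatrix, NormalizedMatrix, PairedExpression

__all__ = ["ConcordanceReport", "pair_platforms", "concordance", "DEFAULT_CT_BINS"]

#: default abundance strata: 5-cycle bins spanning the usual CT range
DEFAULT_CT_BINS: tuple[float, ...] = (15.0, 20.0, 25.0, 30.0, 35.0)


@dataclasses.dataclass
class ConcordanceReport:
    """Overall and CT-binned Spearman concordance of a platform pair."""

    overall_rho: float
    overall_p: float
    bins: pd.DataFrame  # columns ct_lo, ct_hi, n_genes, rho, p
    n_shared: int


def pair_platforms(
    ct: NormalizedMatrix,
    array: pd.DataFrame,
    sample_map: Mapping[str, str],
    raw_ct: CTMatrix | None = None,
) -> dict[str, PairedExpression]:
    """Inner-join dCT with microarray intensity per mapped sample.

    ``sample_map`` maps RT-PCR sample ids to array column names.
    Intensities must be positive; they are log2-transformed here.  When
    ``raw_ct`` is given, each gene's mean raw CT is attached for
    abundance binning; otherwise the dCT values themselves stand in.
    """
    shared = ct.data.index.intersection(array.index)
    if len(shared) == 0:
        raise ValueError("no gene ids shared between the two platforms")
    bad = array.loc[shared][(array.loc[shared] <= 0).any(axis=1)]
    if len(bad):
        raise ValueError(
            f"nonpositive microarray intensity for gene(s) {list(bad.index)}")
    if raw_ct is not None:
        mean_ct = raw_ct.data.reindex(shared).mean(axis=1).to_numpy()
    else:
        mean_ct = None

    out: dict[str, PairedExpression] = {}
    for ct_sample, arr_sample in sample_map.items():
        if ct_sample not in ct.data.columns:
            raise ValueError(f"unknown RT-PCR sample {ct_sample!r}")
        if arr_sample not in array.columns:
            raise ValueError(f"unknown array sample {arr_sample!r}")
        dct = ct.data.loc[shared, ct_sample].to_numpy()
        log2_int = np.log2(array.loc[shared, arr_sample].to_numpy(dtype=float))
        out[ct_sample] = PairedExpression(
            gene_ids=list(shared), delta_ct=dct, log2_intensity=log2_int,
            mean_ct=mean_ct if mean_ct is not None else dct.copy())
    return out


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    # tie-free data: the classic 1 - 6*sum(d^2)/(n(n^2-1)) form, which is
    # exact (+-1 for perfect monotone data); with ties, Pearson on midranks
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(x)
    if len(np.unique(x)) == n and len(np.unique(y)) == n:
        d = rx - ry
        return float(1.0 - 6.0 * (d @ d) / (n * (n * n - 1.0)))
    return float(stats.pearsonr(rx, ry)[0])


def _spearman(x: np.ndarray, y: np.ndarray, n_permutations: int,
              rng: np.random.Generator) -> tuple[float, float]:
    rho = _spearman_rho(x, y)
    p_asym = stats.spearmanr(x, y)[1]
    if len(x) >= 50 or n_permutations <= 0:
        return float(rho), float(p_asym)
    # permutation p for small n (two-sided)
    hits = 0
    for _ in range(n_permutations):
        perm_rho = _spearman_rho(x, rng.permutation(y))
        if abs(perm_rho) >= abs(rho) - 1e-12:
            hits += 1
    return float(rho), (hits + 1) / (n_permutations + 1)


def concordance(
    paired: PairedExpression,
    ct_bins: tuple[float, ...] | None = DEFAULT_CT_BINS,
    *,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> ConcordanceReport:
    """Spearman correlation of dCT with log2 intensity, overall and by
    mean-raw-CT bin (half-open [lo, hi); bins with < 3 genes get NaN).
    """
    dct = np.asarray(paired.delta_ct, dtype=float)
    log2_int = np.asarray(paired.log2_intensity, dtype=float)
    ok = np.isfinite(dct) & np.isfinite(log2_int)
    dct, log2_int = dct[ok], log2_int[ok]
    mean_ct = np.asarray(paired.mean_ct, dtype=float)[ok]
    n_shared = int(ok.sum())
    if n_shared < 3:
        raise ValueError("need >= 3 paired genes")

    rng = np.random.default_rng(seed)
    overall_rho, overall_p = _spearman(dct, log2_int, n_permutations, rng)

    rows = []
    edges = tuple(ct_bins) if ct_bins else ()
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= lo:
            raise ValueError("ct_bins must be strictly ascending")
        sel = (mean_ct >= lo) & (mean_ct < hi)
        n = int(sel.sum())
        if n >= 3:
            rho, p = _spearman(dct[sel], log2_int[sel], n_permutations, rng)
        else:
            rho, p = np.nan, np.nan
        rows.append({"ct_lo": lo, "ct_hi": hi, "n_genes": n, "rho": rho, "p": p})
    bins = pd.DataFrame(rows, columns=["ct_lo", "ct_hi", "n_genes", "rho", "p"])
    return ConcordanceReport(overall_rho=overall_rho, overall_p=overall_p,
                             bins=bins, n_shared=n_shared)
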