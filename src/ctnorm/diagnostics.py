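"""Bias diagnostics for CT matrices.

RT-PCR CT data carry an expression-level-dependent bias: a shared
per-sample loading fluctuation perturbs low-abundance genes (high CT)
more than abundant ones.  The diagnostics here quantify its empirical
signatures: the trend of per-gene sd with mean CT, the correlation of
each gene's fluctuations with the sample-mean fluctuations, the
per-gene regression slope of gene fluctuation on mean fluctuation
(sensitivity), and the mean per-sample ratio of the two fluctuations.

Fluctuations are centered quantities: a gene's fluctuation in a sample
is its CT minus the gene's own mean; a sample's mean fluctuation is the
sample mean minus the overall mean.  On a complete matrix the mean
fluctuation is exactly the gene-average of the gene fluctuations, which
forces the average sensitivity slope to equal 1.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core import CTMatrix

__all__ = [
    "BiasReport",
    "fluctuations",
    "sd_vs_mean_trend",
    "correlation_with_mean",
    "sensitivity_slopes",
    "difference_ratio",
    "bias_report",
]


@dataclasses.dataclass
class BiasReport:
    """Per-gene bias diagnostics plus the sd-vs-mean trend line."""

    table: pd.DataFrame  # index gene ids; columns mean_ct, sd,
    # corr_with_mean, sensitivity_slope, mean_difference_ratio
    trend_slope: float
    trend_intercept: float

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)


def fluctuations(matrix: CTMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene and per-sample-mean centered fluctuations.

    Returns (gene_fluct, mean_fluct): gene_fluct[g, s] = CT[g, s] minus
    gene g's mean over its observed samples; mean_fluct[s] = sample s's
    mean CT minus the average of the sample means.  Each gene row and
    the mean_fluct vector sum to zero over their observed entries.
    """
    if matrix.n_samples < 2:
        raise ValueError("fluctuations need >= 2 samples")
    data = matrix.data
    gene_fluct = data.sub(data.mean(axis=1), axis=0)
    sample_means = data.mean(axis=0)
    mean_fluct = sample_means - sample_means.mean()
    return gene_fluct, mean_fluct


def sd_vs_mean_trend(
    matrix: CTMatrix, min_genes: int = 3
) -> tuple[float, float, pd.DataFrame]:
    """OLS fit of per-gene sd on per-gene mean CT.

    Returns (slope, intercept, points) where points has columns mean_ct
    and sd per gene with a defined sd.
    """
    mean_ct = matrix.data.mean(axis=1)
    n_obs = matrix.data.notna().sum(axis=1)
    sd = matrix.data.std(axis=1, ddof=1).where(n_obs >= 2)
    points = pd.DataFrame({"mean_ct": mean_ct, "sd": sd}).dropna()
    if len(points) < min_genes:
        raise ValueError(
            f"need >= {min_genes} genes with a defined sd, got {len(points)}")
    x = points["mean_ct"].to_numpy()
    y = points["sd"].to_numpy()
    if np.ptp(x) == 0:  # degenerate design: all genes at the same mean CT
        return 0.0, float(np.mean(y)), points
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept), points


def _per_gene_regression(matrix: CTMatrix):
    """Yield per-gene (x, y) pairs of (mean fluctuation, gene fluctuation),
    re-centered over the gene's observed samples when wells are missing."""
    gene_fluct, mean_fluct = fluctuations(matrix)
    mf = mean_fluct.to_numpy()
    for gene in matrix.data.index:
        row = matrix.data.loc[gene].to_numpy()
        obs = ~np.isnan(row)
        x = mf[obs] - mf[obs].mean()
        y = row[obs] - row[obs].mean()
        yield gene, x, y


def correlation_with_mean(matrix: CTMatrix) -> pd.Series:
    """Pearson correlation of each gene's fluctuations with the
    sample-mean fluctuations; NaN for zero-variance genes (undefined)."""
    if matrix.n_samples < 3:
        raise ValueError("correlation needs >= 3 samples")
    out = {}
    for gene, x, y in _per_gene_regression(matrix):
        sx = np.sqrt((x * x).sum())
        sy = np.sqrt((y * y).sum())
        out[gene] = (x @ y) / (sx * sy) if sx > 0 and sy > 0 else np.nan
    return pd.Series(out, name="corr_with_mean").reindex(matrix.data.index)


def sensitivity_slopes(matrix: CTMatrix) -> pd.Series:
    """Per-gene OLS slope of gene fluctuation on mean fluctuation.

    Both variables are centered, so the fitted intercept is zero; the
    slope quantifies how strongly a gene responds to a shared loading
    fluctuation (1 = moves with the mean, >1 = amplifies it).
    """
    if matrix.n_samples < 3:
        raise ValueError("sensitivity slopes need >= 3 samples")
    _, mean_fluct = fluctuations(matrix)
    if np.allclose(mean_fluct.to_numpy(), 0.0):
        raise ValueError(
            "mean fluctuation is identically zero (degenerate design)")
    out = {}
    for gene, x, y in _per_gene_regression(matrix):
        sxx = (x * x).sum()
        out[gene] = (x @ y) / sxx if sxx > 0 else np.nan
    return pd.Series(out, name="sensitivity_slope").reindex(matrix.data.index)


def difference_ratio(matrix: CTMatrix, guard: float = 0.05) -> pd.Series:
    """Mean per-sample ratio of gene fluctuation to mean fluctuation.

    Samples whose |mean fluctuation| falls below ``guard`` (cycles) are
    excluded, since the ratio blows up near zero.
    """
    gene_fluct, mean_fluct = fluctuations(matrix)
    mf = mean_fluct.to_numpy()
    qualify = np.abs(mf) >= guard
    if not qualify.any():
        raise ValueError(
            f"no sample has |mean fluctuation| >= {guard}; lower the guard")
    gf = gene_fluct.to_numpy()
    with np.errstate(invalid="ignore"):
        ratios = gf[:, qualify] / mf[qualify][None, :]
    mean_ratio = np.nanmean(ratios, axis=1)
    return pd.Series(mean_ratio, index=matrix.data.index,
                     name="mean_difference_ratio")


def bias_report(matrix: CTMatrix, guard: float = 0.05) -> BiasReport:
    """Assemble all per-gene diagnostics and the sd-vs-mean trend line.

    On a degenerate matrix (zero mean fluctuation) the fluctuation-based
    columns are reported as NaN rather than raising.
    """
    mean_ct = matrix.data.mean(axis=1)
    n_obs = matrix.data.notna().sum(axis=1)
    sd = matrix.data.std(axis=1, ddof=1).where(n_obs >= 2)
    try:
        trend_slope, trend_intercept, _ = sd_vs_mean_trend(matrix)
    except ValueError:
        trend_slope, trend_intercept = np.nan, np.nan

    index = matrix.data.index
    _, mean_fluct = fluctuations(matrix)
    degenerate = np.allclose(mean_fluct.to_numpy(), 0.0)
    if degenerate:
        nancol = pd.Series(np.nan, index=index)
        corr, slopes, ratios = nancol, nancol.copy(), nancol.copy()
    else:
        corr = correlation_with_mean(matrix)
        slopes = sensitivity_slopes(matrix)
        try:
            ratios = difference_ratio(matrix, guard=guard)
        except ValueError:
            ratios = pd.Series(np.nan, index=index)

    table = pd.DataFrame({
        "mean_ct": mean_ct,
        "sd": sd,
        "corr_with_mean": corr,
        "sensitivity_slope": slopes,
        "mean_difference_ratio": ratios,
    })
    return BiasReport(table=table, trend_slope=trend_slope,
                      trend_intercept=trend_intercept)
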