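"""Synthetic CT matrices with the expression-level-dependent bias of
real RT-PCR panels.

Generating model:

    CT[g, s] = mu_g + s_g * delta_s + eps[g, s],   eps ~ N(0, sigma_g^2)

where mu_g is gene g's true mean CT, delta_s a per-sample loading
offset (mean zero), s_g = a + b * mu_g the gene's sensitivity to that
offset, and sigma_g = c + d * mu_g the gene's measurement noise sd.
With b > 0 and d > 0 the model reproduces the signatures seen in real
low-density-array data: per-gene sd grows with mean CT, every gene's
fluctuations correlate with the sample-mean fluctuations, and
low-abundance (high-CT) genes respond more strongly to loading
fluctuations.

Defaults mirror a typical low-density-array study: 666 genes by 20
samples, mean CT uniform on 15-35 cycles, loading offsets with sd 0.6
cycles, and coefficients chosen so the gene-averaged sensitivity is 1
(the fluctuation regression identifies sensitivities only relative to
their mean) and per-gene sds land in the 0.4-0.9 cycle range.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core import CTMatrix

__all__ = ["SyntheticTruth", "generate_ct", "generate_paired", "spike_undetected"]

DEFAULT_N_GENES = 666
DEFAULT_N_SAMPLES = 20
DEFAULT_MEAN_RANGE = (15.0, 35.0)
DEFAULT_OFFSET_SD = 0.6
DEFAULT_SENSITIVITY_COEF = (-0.5, 0.06)  # a + b*mu; mean sensitivity 1 at mu=25
DEFAULT_NOISE_COEF = (0.1, 0.02)  # c + d*mu; sd 0.4 at mu=15, 0.8 at mu=35


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth behind a simulated CT matrix."""

    gene_ids: list[str]
    sample_ids: list[str]
    gene_means: np.ndarray       # mu_g, cycles
    sample_offsets: np.ndarray   # delta_s, cycles, sums to 0
    sensitivities: np.ndarray    # s_g
    noise_sd: np.ndarray         # sigma_g, cycles
    sensitivity_coef: tuple[float, float] | None
    noise_coef: tuple[float, float] | None
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_mean": self.gene_means,
            "sensitivity": self.sensitivities,
            "noise_sd": self.noise_sd,
        }, index=self.gene_ids)


def generate_ct(
    n_genes: int = DEFAULT_N_GENES,
    n_samples: int = DEFAULT_N_SAMPLES,
    *,
    mean_range: tuple[float, float] = DEFAULT_MEAN_RANGE,
    offset_sd: float = DEFAULT_OFFSET_SD,
    sensitivity_coef: tuple[float, float] = DEFAULT_SENSITIVITY_COEF,
    noise_coef: tuple[float, float] = DEFAULT_NOISE_COEF,
    gene_means: np.ndarray | None = None,
    sensitivities: np.ndarray | None = None,
    noise_sd: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[CTMatrix, SyntheticTruth]:
    """Simulate a CT matrix under the loading-offset bias model.

    Per-gene means, sensitivities and noise sds default to the linear
    forms above but can each be supplied explicitly as arrays (useful
    for parameter-recovery studies with designed sensitivity groups).
    Deterministic given ``seed``.
    """
    if n_genes < 2 or n_samples < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    rng = np.random.default_rng(seed)

    if gene_means is None:
        gene_means = rng.uniform(*mean_range, size=n_genes)
    else:
        gene_means = np.asarray(gene_means, dtype=float)
        if gene_means.shape != (n_genes,):
            raise ValueError("gene_means must have length n_genes")

    if sensitivities is None:
        a, b = sensitivity_coef
        sensitivities = a + b * gene_means
    else:
        sensitivities = np.asarray(sensitivities, dtype=float)
        sensitivity_coef = None
    if np.any(sensitivities <= 0):
        raise ValueError("sensitivities must be positive over the mean-CT range")

    if noise_sd is None:
        c, d = noise_coef
        noise_sd = c + d * gene_means
    else:
        noise_sd = np.asarray(noise_sd, dtype=float)
        noise_coef = None
    if np.any(noise_sd <= 0):
        raise ValueError("noise sds must be positive over the mean-CT range")

    offsets = rng.normal(0.0, offset_sd, size=n_samples)
    offsets = offsets - offsets.mean()
    eps = rng.normal(0.0, 1.0, size=(n_genes, n_samples)) * noise_sd[:, None]
    values = gene_means[:, None] + sensitivities[:, None] * offsets[None, :] + eps

    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    sample_ids = [f"s{j:02d}" for j in range(n_samples)]
    matrix = CTMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
    truth = SyntheticTruth(
        gene_ids=gene_ids, sample_ids=sample_ids,
        gene_means=gene_means, sample_offsets=offsets,
        sensitivities=np.asarray(sensitivities, dtype=float),
        noise_sd=np.asarray(noise_sd, dtype=float),
        sensitivity_coef=sensitivity_coef, noise_coef=noise_coef, seed=seed)
    return matrix, truth


def generate_paired(
    truth: SyntheticTruth,
    concordance_noise: float = 0.0,
    *,
    intensity_offset: float = 40.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Microarray-style intensities paired to a synthetic CT matrix.

    Intensities follow 2**(K - mu_g + noise) with K = intensity_offset,
    so log2 intensity is linear in -mu_g: genes abundant on the PCR
    platform (low CT) are bright on the array, up to Gaussian noise on
    the log2 scale.  Deterministic given the seed (defaults to
    ``truth.seed + 1``).
    """
    if concordance_noise < 0:
        raise ValueError("concordance_noise must be nonnegative")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    n_genes = len(truth.gene_ids)
    n_samples = len(truth.sample_ids)
    noise = (rng.normal(0.0, concordance_noise, size=(n_genes, n_samples))
             if concordance_noise > 0 else np.zeros((n_genes, n_samples)))
    log2_int = intensity_offset - truth.gene_means[:, None] + noise
    return pd.DataFrame(np.exp2(log2_int), index=truth.gene_ids,
                        columns=truth.sample_ids)


def spike_undetected(
    matrix: CTMatrix,
    fraction: float,
    bias_toward_high_ct: bool = False,
    seed: int = 0,
) -> CTMatrix:
    """Set a fixed fraction of wells to the undetected sentinel.

    Exactly ``round(fraction * n_cells)`` cells are chosen (without
    replacement) and set to ``matrix.undetected_ct``.  In biased mode a
    cell's selection probability is proportional to the rank of its
    gene's mean CT, mimicking dropout concentrating in low-abundance
    genes.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    n_cells = matrix.n_genes * matrix.n_samples
    n_spike = int(round(fraction * n_cells))
    if n_spike == 0:
        return CTMatrix(matrix.data.copy(), undetected_ct=matrix.undetected_ct)
    rng = np.random.default_rng(seed)
    if bias_toward_high_ct:
        gene_rank = matrix.data.mean(axis=1).rank(method="first").to_numpy()
        cell_w = np.repeat(gene_rank, matrix.n_samples)
        p = cell_w / cell_w.sum()
    else:
        p = None
    chosen = rng.choice(n_cells, size=n_spike, replace=False, p=p)
    values = matrix.data.to_numpy().copy()
    flat = values.reshape(-1)
    flat[chosen] = matrix.undetected_ct
    return CTMatrix(pd.DataFrame(values, index=matrix.data.index,
                                 columns=matrix.data.columns),
                    undetected_ct=matrix.undetected_ct)
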