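"""Stability scoring of genes and candidate pseudo-controls.

Two criteria are used throughout: the across-sample standard deviation
of a gene's CT, and a geNorm-style M value — the average, over all
partner genes, of the standard deviation of the pairwise CT difference.
CT is already log-scale in abundance, so CT differences play the role
the log expression ratios play in the original geNorm measure; lower M
means more stable.  A candidate CT0 vector is scored by appending it to
the gene set as a pseudo-gene.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .core import CTMatrix, CT0Vector
from .normalize import weighted_mean_ct0, WeightedMeanParams

__all__ = [
    "StabilityReport",
    "WmpScan",
    "genorm_m",
    "rank_genes",
    "evaluate_ct0",
    "scan_wmp",
    "DEFAULT_POWER_GRID",
]

logger = logging.getLogger(__name__)

#: powers evaluated by default in :func:`scan_wmp`: 0 plus the odd values 1..19
DEFAULT_POWER_GRID: tuple[float, ...] = (0.0,) + tuple(float(p) for p in range(1, 20, 2))


@dataclasses.dataclass
class StabilityReport:
    """Per-entry mean CT, sd and geNorm M, sorted by the chosen criterion."""

    table: pd.DataFrame  # index entry ids; columns mean_ct, sd, genorm_m
    criterion: str

    @property
    def entry_ids(self) -> list[str]:
        return list(self.table.index)


@dataclasses.dataclass
class WmpScan:
    """Stability of the weighted-mean CT0 across a grid of powers."""

    powers: np.ndarray
    sd_of_ct0: np.ndarray
    genorm_of_ct0: np.ndarray
    best_power_by_sd: float
    best_power_by_genorm: float
    epsilon: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "power": self.powers,
            "sd_of_ct0": self.sd_of_ct0,
            "genorm_of_ct0": self.genorm_of_ct0,
        })


def _pairwise_m(values: np.ndarray, ids: list[str]) -> pd.Series:
    """Average pairwise-variation M per row of a genes x samples array."""
    n_genes = values.shape[0]
    if n_genes < 2:
        raise ValueError("geNorm M needs at least 2 entries")
    mask = np.isnan(values)
    if not mask.any():
        # V_jk = sd(CT_j - CT_k) via the covariance matrix
        C = np.cov(values, ddof=1)
        d = np.diag(C)
        V2 = d[:, None] + d[None, :] - 2.0 * C
        V = np.sqrt(np.clip(V2, 0.0, None))
        np.fill_diagonal(V, np.nan)
        with np.errstate(invalid="ignore"):
            m = np.nanmean(V, axis=1)
        return pd.Series(m, index=ids, name="genorm_m")

    m = np.full(n_genes, np.nan)
    for j in range(n_genes):
        vs = []
        for k in range(n_genes):
            if k == j:
                continue
            both = ~mask[j] & ~mask[k]
            if both.sum() < 2:
                continue  # pair skipped: fewer than 2 overlapping samples
            vs.append(np.std(values[j, both] - values[k, both], ddof=1))
        if vs:
            m[j] = float(np.mean(vs))
    out = pd.Series(m, index=ids, name="genorm_m")
    dropped = out.index[out.isna()].tolist()
    if dropped:
        logger.warning("entries with no valid geNorm pairs omitted: %s", dropped)
    return out.dropna()


def genorm_m(matrix: CTMatrix, candidate: CT0Vector | None = None,
             candidate_label: str = "CT0") -> pd.Series:
    """geNorm-style M per gene (and per candidate pseudo-gene, if given).

    M_j is the mean over partners k of sd over samples of (CT_j - CT_k),
    each pair computed on the samples where both entries are observed.
    """
    if matrix.n_samples < 2:
        raise ValueError("geNorm M needs at least 2 samples")
    values = matrix.values
    ids = matrix.gene_ids
    if candidate is not None:
        if list(candidate.values.index) != matrix.sample_ids:
            raise ValueError("candidate CT0 sample ids do not match the matrix")
        values = np.vstack([values, candidate.values.to_numpy()[None, :]])
        ids = ids + [candidate_label]
    return _pairwise_m(values, ids)


def rank_genes(matrix: CTMatrix, criterion: str = "sd") -> StabilityReport:
    """Rank genes by increasing sd or geNorm M (ties broken by gene id)."""
    if criterion not in {"sd", "genorm"}:
        raise ValueError(f"unknown criterion {criterion!r}")
    mean_ct = matrix.data.mean(axis=1)
    sd = matrix.data.std(axis=1, ddof=1)
    m = genorm_m(matrix) if matrix.n_genes >= 2 else pd.Series(dtype=float)
    table = pd.DataFrame({"mean_ct": mean_ct, "sd": sd})
    table["genorm_m"] = m
    key = "sd" if criterion == "sd" else "genorm_m"
    table = table.dropna(subset=[key])
    # stable sort on the criterion after an index sort => ties break by gene id
    table = table.sort_index(kind="mergesort").sort_values(key, kind="mergesort")
    return StabilityReport(table=table, criterion=criterion)


def evaluate_ct0(matrix: CTMatrix, ct0: CT0Vector,
                 label: str = "CT0") -> tuple[float, float, float]:
    """(mean, sd, geNorm M) of a candidate CT0 across samples."""
    vals = ct0.values.to_numpy()
    m = genorm_m(matrix, candidate=ct0, candidate_label=label)
    return (float(np.mean(vals)), float(np.std(vals, ddof=1)),
            float(m.loc[label]))


def scan_wmp(matrix: CTMatrix, powers=None, epsilon: float = 0.01) -> WmpScan:
    """Evaluate the weighted-mean CT0 over a grid of powers.

    For each power the CT0 vector is recomputed and scored by its
    across-sample sd and its geNorm M against all genes; the best power
    under each criterion is reported (ties go to the smallest power).
    """
    if powers is None:
        powers = DEFAULT_POWER_GRID
    powers = np.asarray(list(powers), dtype=float)
    if powers.size == 0:
        raise ValueError("powers must be non-empty")
    sds = np.empty_like(powers)
    ms = np.empty_like(powers)
    for i, p in enumerate(powers):
        ct0 = weighted_mean_ct0(matrix, WeightedMeanParams(wmp=p, epsilon=epsilon))
        _, sds[i], ms[i] = evaluate_ct0(matrix, ct0)
    return WmpScan(
        powers=powers,
        sd_of_ct0=sds,
        genorm_of_ct0=ms,
        best_power_by_sd=float(_argmin_smallest_power(powers, sds)),
        best_power_by_genorm=float(_argmin_smallest_power(powers, ms)),
        epsilon=epsilon,
    )


def _argmin_smallest_power(powers: np.ndarray, scores: np.ndarray) -> float:
    best = np.min(scores)
    return float(np.min(powers[scores == best]))
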