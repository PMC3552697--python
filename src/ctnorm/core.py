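"""Containers and delimited-text I/O for RT-PCR cycle-threshold (CT) data.

The universal input is a CT matrix: genes (miRNAs) in rows, samples in
columns, values in PCR cycles.  Wells that never crossed the detection
threshold are conventionally exported at the instrument's maximum cycle
count (usually 40); such wells are either dropped to NaN on read or kept
and handled by an explicit filtering policy downstream.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CTMatrix",
    "CT0Vector",
    "NormalizedMatrix",
    "PairedExpression",
    "read_ct_matrix",
    "write_matrix",
    "filter_genes",
]

#: token written for (and accepted as) a missing cell, besides the empty cell
MISSING_TOKEN = "NA"


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups}")


@dataclasses.dataclass
class CTMatrix:
    """Genes x samples matrix of raw CT values.

    Parameters
    ----------
    data : pandas.DataFrame
        Float values in cycles, index = gene ids, columns = sample ids,
        NaN marks a missing (e.g. undetected and dropped) well.
    undetected_ct : float
        Sentinel cycle value at or above which a well is treated as
        undetected.  Default 40.0 cycles.
    """

    data: pd.DataFrame
    undetected_ct: float = 40.0

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        vals = self.data.to_numpy()
        finite = np.isfinite(vals)
        if np.any(vals[finite] <= 0):
            raise ValueError("CT values must be positive (cycles)")
        if np.any(np.isinf(vals)):
            raise ValueError("CT values must be finite or NaN")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()


@dataclasses.dataclass
class CT0Vector:
    """One pseudo-control CT value per sample (the value subtracted to form dCT)."""

    values: pd.Series  # index = sample ids
    method: str
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "sample ids")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("CT0 values must be finite")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


@dataclasses.dataclass
class NormalizedMatrix:
    """dCT (or adjusted-CT) matrix with provenance of the producing method."""

    data: pd.DataFrame
    method: str
    scale: str  # "delta_ct" or "adjusted_ct"
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in {"delta_ct", "adjusted_ct"}:
            raise ValueError(f"unknown scale {self.scale!r}")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclasses.dataclass
class PairedExpression:
    """Per-gene dCT paired with log2 microarray intensity for one sample pair.

    ``mean_ct`` carries each gene's mean raw CT so concordance can be
    binned by abundance; it falls back to the dCT values themselves when
    no raw matrix was supplied at pairing time.
    """

    gene_ids: list[str]
    delta_ct: np.ndarray
    log2_intensity: np.ndarray
    mean_ct: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if len(self.delta_ct) != n or len(self.log2_intensity) != n:
            raise ValueError("paired vectors must match the shared gene list")
        if self.mean_ct is not None and len(self.mean_ct) != n:
            raise ValueError("mean_ct length must match the shared gene list")


# ---------------------------------------------------------------------------
# I/O


def read_ct_matrix(
    path: str | Path,
    layout: str = "wide",
    *,
    delimiter: str | None = None,
    missing_token: str = MISSING_TOKEN,
    undetected_ct: float = 40.0,
    drop_undetected: bool = True,
) -> CTMatrix:
    """Read a CT matrix from delimited text.

    Wide layout: first column gene ids, header row sample ids.
    Long layout: columns (gene, sample, ct) in any row order.

    Cells equal to ``missing_token`` or empty parse as missing.  With
    ``drop_undetected`` (the default), values >= ``undetected_ct`` are
    additionally set missing; otherwise they are retained as-is.
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    na_values = [missing_token, ""]
    if layout == "wide":
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                         na_values=na_values, keep_default_na=False)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        parsed = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
        bad = parsed.isna() & df.notna()
        if bad.to_numpy().any():
            gene = bad.index[bad.any(axis=1)][0]
            col = bad.columns[bad.loc[gene]][0]
            raise ValueError(
                f"non-numeric CT value {df.loc[gene, col]!r} at gene "
                f"{gene!r}, sample {col!r}")
        data = parsed
        data.index.name = None
        data.columns.name = None
    elif layout == "long":
        df = pd.read_csv(path, sep=sep, dtype=str, na_values=na_values,
                         keep_default_na=False)
        if df.shape[1] < 3:
            raise ValueError("long layout requires columns (gene, sample, ct)")
        gene_col, sample_col, ct_col = df.columns[:3]
        pairs = df[[gene_col, sample_col]]
        if pairs.duplicated().any():
            dup = pairs[pairs.duplicated()].iloc[0]
            raise ValueError(
                f"duplicate (gene, sample) pair in long layout: "
                f"({dup[gene_col]!r}, {dup[sample_col]!r})")
        ct = [
            _parse_ct(tok, g, s)
            for g, s, tok in zip(df[gene_col], df[sample_col], df[ct_col])
        ]
        long = pd.DataFrame({"gene": df[gene_col].astype(str),
                             "sample": df[sample_col].astype(str),
                             "ct": ct})
        data = long.pivot(index="gene", columns="sample", values="ct")
        data = data.sort_index(axis=0).sort_index(axis=1)
        data.index.name = None
        data.columns.name = None
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if drop_undetected:
        data = data.mask(data >= undetected_ct)
    return CTMatrix(data, undetected_ct=undetected_ct)


def _parse_ct(token, gene: str, sample: str) -> float:
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return np.nan
    try:
        return float(token)
    except (TypeError, ValueError):
        raise ValueError(
            f"non-numeric CT value {token!r} at gene {gene!r}, sample {sample!r}"
        ) from None


def write_matrix(
    matrix: CTMatrix | NormalizedMatrix,
    path: str | Path,
    layout: str = "wide",
    *,
    delimiter: str | None = None,
) -> None:
    """Write a CT or normalized matrix as delimited text (full float precision)."""
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    data = matrix.data
    if layout == "wide":
        out = data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep=sep, na_rep=MISSING_TOKEN)
    elif layout == "long":
        long = data.stack(future_stack=True).reset_index()
        long.columns = ["gene_id", "sample_id", "ct"]
        long.to_csv(path, sep=sep, index=False, na_rep=MISSING_TOKEN)
    else:
        raise ValueError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# Filtering


def filter_genes(
    matrix: CTMatrix,
    policy: str = "drop_any_missing",
    max_missing_fraction: float | None = None,
) -> CTMatrix:
    """Return a submatrix of genes passing a missingness policy.

    Policies: ``drop_any_missing`` removes genes with any missing well;
    ``drop_all_missing`` removes only genes missing everywhere;
    ``max_missing_fraction`` keeps genes whose missing fraction is <= the
    threshold (boundary inclusive).
    """
    missing_frac = matrix.data.isna().mean(axis=1)
    if policy == "drop_any_missing":
        keep = missing_frac == 0
    elif policy == "drop_all_missing":
        keep = missing_frac < 1
    elif policy == "max_missing_fraction":
        if max_missing_fraction is None or not 0 <= max_missing_fraction <= 1:
            raise ValueError("max_missing_fraction requires a threshold in [0, 1]")
        keep = missing_frac <= max_missing_fraction
    else:
        raise ValueError(f"unknown policy {policy!r}")
    if not keep.any():
        raise ValueError(
            "filtering removed every gene; relax the policy or raise the "
            "missing-fraction threshold")
    return CTMatrix(matrix.data.loc[keep], undetected_ct=matrix.undetected_ct)
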