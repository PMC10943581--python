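"""Phenotype preprocessing: missingness filters, minimum imputation,
inverse-normal transform, and log-ratio construction.

Protein matrices are pandas DataFrames (rows = samples, columns = proteins)
holding log-scale abundances with NaN for missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_missingness",
    "impute_minimum",
    "inverse_normal_transform",
    "make_ratio_phenotype",
]


def filter_missingness(
    matrix: pd.DataFrame,
    sample_max_missing: float = 0.2,
    protein_max_missing: float = 0.2,
) -> pd.DataFrame:
    """Drop high-missingness samples, then high-missingness proteins.

    The order is normative: samples with missing fraction strictly above
    ``sample_max_missing`` are removed first, and protein missingness is
    evaluated on the retained samples only.  Both comparisons are strict, so
    a threshold of 1.0 never drops anything.
    """
    for name, v in (
        ("sample_max_missing", sample_max_missing),
        ("protein_max_missing", protein_max_missing),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    sample_miss = matrix.isna().mean(axis=1)
    out = matrix.loc[sample_miss <= sample_max_missing]
    if out.shape[0] == 0:
        raise ValueError(
            f"sample filter (> {sample_max_missing:g} missing) removed all "
            f"{matrix.shape[0]} samples"
        )
    protein_miss = out.isna().mean(axis=0)
    out = out.loc[:, protein_miss <= protein_max_missing]
    if out.shape[1] == 0:
        raise ValueError(
            f"protein filter (> {protein_max_missing:g} missing) removed all "
            f"{matrix.shape[1]} proteins"
        )
    return out


def impute_minimum(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace each missing value by the per-protein observed minimum."""
    all_missing = matrix.columns[matrix.isna().all(axis=0)]
    if len(all_missing):
        raise ValueError(
            f"cannot impute all-missing protein(s): {list(all_missing)}"
        )
    return matrix.fillna(matrix.min(axis=0))


def inverse_normal_transform(values: pd.Series | np.ndarray) -> pd.Series:
    """Rank-based inverse-normal transform with the Blom offset.

    Non-missing entries are mapped to Phi^-1((r - 3/8) / (m + 1/4)) where r
    is the average rank among the m observed values; missing entries stay
    missing.  Ties receive equal transformed values.
    """
    ser = pd.Series(np.asarray(values, dtype=float)) if not isinstance(
        values, pd.Series
    ) else values.astype(float)
    obs = ser.notna()
    m = int(obs.sum())
    if m < 3:
        raise ValueError(f"need >= 3 non-missing values, got {m}")
    ranks = stats.rankdata(ser[obs].to_numpy())
    quantiles = (ranks - 0.375) / (m + 0.25)
    out = ser.copy()
    out[obs] = stats.norm.ppf(quantiles)
    return out


def make_ratio_phenotype(
    matrix: pd.DataFrame, pair: tuple[str, str]
) -> pd.Series:
    """Inverse-normal transformed log-ratio phenotype for a protein pair.

    Since the abundances are on a log scale the ratio phenotype is the
    plain difference of the two columns, missing wherever either protein is
    missing, then inverse-normal transformed.
    """
    num, den = pair
    for pid in (num, den):
        if pid not in matrix.columns:
            raise KeyError(f"unknown protein id: {pid!r}")
    if num == den:
        raise ValueError(f"ratio requires two distinct proteins, got {num!r}")
    diff = matrix[num] - matrix[den]
    observed = diff.dropna()
    if len(observed) and float(observed.std(ddof=0)) == 0.0:
        raise ValueError(
            f"degenerate ratio {num}/{den}: difference has zero variance"
        )
    out = inverse_normal_transform(diff)
    out.name = f"{num}/{den}"
    return out
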