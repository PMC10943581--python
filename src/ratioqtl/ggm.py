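"""Gaussian graphical model edges from shrinkage partial correlations.

The correlation matrix is shrunk toward the identity with the analytic
Schafer-Strimmer intensity before inversion, which keeps the estimate
well-conditioned even when proteins outnumber samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "PcorEdge",
    "estimate_pcor_shrinkage",
    "pcor_pvalues",
    "significant_edges",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class PcorEdge:
    """A partial-correlation edge between two proteins (a < b)."""

    a: str
    b: str
    pcor: float
    neglog10_p: float
    significant: bool

    def __post_init__(self) -> None:
        if not self.a < self.b:
            raise ValueError(f"edge proteins must be ordered: {self.a!r} vs {self.b!r}")
        if abs(self.pcor) > 1.0:
            raise ValueError(f"|pcor| > 1: {self.pcor}")


def _optimal_shrinkage(x: np.ndarray) -> float:
    """Analytic optimal intensity for shrinking correlations toward zero.

    lambda* = sum_{i<j} Var(r_ij) / sum_{i<j} r_ij^2, estimated from the
    empirical variance of the standardized cross-products, clipped to [0,1].
    """
    n = x.shape[0]
    xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    s1 = xs.T @ xs                      # (n-1) * r
    s2 = (xs**2).T @ (xs**2)            # sum_k w_kij^2
    r = s1 / (n - 1)
    var_r = n / (n - 1.0) ** 3 * (s2 - s1**2 / n)
    mask = ~np.eye(x.shape[1], dtype=bool)
    denom = float((r[mask] ** 2).sum())
    if denom == 0.0:
        return 1.0
    return float(np.clip(var_r[mask].sum() / denom, 0.0, 1.0))


def estimate_pcor_shrinkage(
    matrix: pd.DataFrame, shrinkage: float | None = None
) -> tuple[pd.DataFrame, float]:
    """Partial correlations from a shrunk correlation matrix.

    Returns the symmetric partial-correlation matrix (unit diagonal) and
    the shrinkage intensity used.  ``shrinkage=None`` selects the analytic
    optimum; passing 0 reproduces plain precision-matrix standardization
    and fails if the sample correlation matrix is singular.
    """
    if matrix.isna().any().any():
        raise ValueError("protein matrix must be complete; impute first")
    n, p = matrix.shape
    if n <= 3:
        raise ValueError(f"need more than 3 samples, got {n}")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = list(matrix.columns[sd == 0])
        raise ValueError(f"zero-variance protein(s): {bad}")
    r = np.corrcoef(x, rowvar=False)
    lam = _optimal_shrinkage(x) if shrinkage is None else float(shrinkage)
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"shrinkage must be in [0, 1], got {lam}")
    r_star = (1.0 - lam) * r
    np.fill_diagonal(r_star, 1.0)
    try:
        omega = np.linalg.inv(r_star)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"shrunk correlation matrix singular at lambda={lam}"
        ) from exc
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    pcor = (pcor + pcor.T) / 2.0
    return (
        pd.DataFrame(pcor, index=matrix.columns, columns=matrix.columns),
        lam,
    )


def pcor_pvalues(pcor: pd.DataFrame, n: int, p: int) -> pd.DataFrame:
    """Two-sided -log10 p for each partial correlation via Fisher's z.

    z = atanh(pcor) * sqrt(n - 3 - (p - 2)); the effective degrees of
    freedom are floored at 3.  The normal tail is evaluated in log space so
    extreme correlations keep finite, accurate -log10 p.
    """
    if n < 10:
        raise ValueError(f"need n >= 10 samples, got {n}")
    kappa = max(n - 3 - (p - 2), 3)
    vals = pcor.to_numpy(dtype=float)
    out = np.empty_like(vals)
    unit = np.abs(vals) >= 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(np.arctanh(np.where(unit, 0.0, vals))) * math.sqrt(kappa)
    out = -(special.log_ndtr(-z) + math.log(2.0)) / _LN10
    out[unit] = np.inf
    np.fill_diagonal(out, 0.0)
    out = np.maximum(out, 0.0)
    return pd.DataFrame(out, index=pcor.index, columns=pcor.columns)


def significant_edges(
    pcor: pd.DataFrame,
    neglog10_p: pd.DataFrame,
    n_proteins: int,
    alpha: float = 0.05,
) -> list[PcorEdge]:
    """Bonferroni-significant edges among all unordered protein pairs.

    The significance cut is p < alpha / (n_proteins choose 2).  Returned
    edges are sorted by -log10 p descending, proteins within an edge in
    lexicographic order.
    """
    if n_proteins < 2:
        raise ValueError(f"need at least 2 proteins, got {n_proteins}")
    n_pairs = n_proteins * (n_proteins - 1) // 2
    cut = -math.log10(alpha / n_pairs)
    cols = list(pcor.columns)
    edges = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            nlp = float(neglog10_p.iloc[i, j])
            if nlp > cut:
                a, b = sorted((cols[i], cols[j]))
                edges.append(
                    PcorEdge(a, b, float(pcor.iloc[i, j]), nlp, True)
                )
    edges.sort(key=lambda e: (-e.neglog10_p, e.a, e.b))
    return edges
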