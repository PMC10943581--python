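"""The p-gain statistic on the log10 scale, its Bonferroni-style critical
values, and Monte-Carlo calibration under the two-random-proteins null.

The p-gain of a ratio association is the smaller single-protein p-value
divided by the ratio p-value; everything here stays on the -log10 scale so
no raw p-value is ever materialized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .assoc import neglog10_p_from_t

__all__ = [
    "NullCalibration",
    "PgainResult",
    "log10_pgain",
    "pgain_threshold",
    "simulate_null_pgain",
]


@dataclass(frozen=True)
class PgainResult:
    """The three -log10 p values of a ratio test and the derived p-gain."""

    neglog10_p1: float
    neglog10_p2: float
    neglog10_p3: float
    log10_pgain: float
    n_tests: int = 1
    significant: bool = False


@dataclass(frozen=True)
class NullCalibration:
    """Exceedance of the nominal p-gain critical value under a null."""

    exceedance: float
    ci_low: float
    ci_high: float
    n_reps: int
    seed: int


def log10_pgain(
    neglog10_p1: float, neglog10_p2: float, neglog10_p3: float
) -> float:
    """log10 p-gain = -log10 p_ratio - max(-log10 p1, -log10 p2)."""
    for v in (neglog10_p1, neglog10_p2, neglog10_p3):
        if math.isnan(v) or (math.isinf(v) and v < 0):
            raise ValueError(f"invalid -log10 p input: {v!r}")
    return neglog10_p3 - max(neglog10_p1, neglog10_p2)


def pgain_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Critical log10 p-gain for ``n_tests`` Bonferroni-corrected tests.

    The critical p-gain is n_tests / (2 * alpha): 10 for a single test at
    alpha = 0.05, and 10 * B when B tests are performed.
    """
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return math.log10(n_tests / (2.0 * alpha))


def _regress_rows(y: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Row-wise simple OLS of y on g (with intercept); returns -log10 p."""
    n = y.shape[1]
    gc = g - g.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sgg = (gc**2).sum(axis=1)
    sgy = (gc * yc).sum(axis=1)
    syy = (yc**2).sum(axis=1)
    beta = sgy / sgg
    rss = np.maximum(syy - beta * sgy, 0.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta * np.sqrt(sgg * df / rss)
    out = np.empty(y.shape[0])
    for i, t in enumerate(tstat):
        out[i] = (
            math.inf if not np.isfinite(t) else neglog10_p_from_t(t, df)
        )
    return out


def simulate_null_pgain(
    n_samples: int,
    n_reps: int,
    maf: float = 0.3,
    protein_correlation: float = 0.0,
    seed: int = 0,
    beta1: float = 0.0,
    beta2: float = 0.0,
) -> NullCalibration:
    """Fraction of replicates whose p-gain exceeds the single-test critical
    value of 10.

    Each replicate draws an independent biallelic SNP (Binomial(2, maf))
    and a bivariate-normal protein pair with correlation rho; optional
    per-allele effects ``beta1``/``beta2`` turn the null into a power
    scenario.  The ratio phenotype is the inverse-normal transformed
    difference, as in the real analysis.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    rho = protein_correlation
    if abs(rho) >= 1.0:
        raise ValueError(f"|protein correlation| must be < 1, got {rho}")

    rng = np.random.default_rng(seed)
    g = rng.binomial(2, maf, size=(n_reps, n_samples)).astype(float)
    z1 = rng.standard_normal((n_reps, n_samples))
    z2 = rng.standard_normal((n_reps, n_samples))
    p1 = z1 + beta1 * g
    p2 = rho * z1 + math.sqrt(1.0 - rho * rho) * z2 + beta2 * g
    diff = p1 - p2
    ranks = stats.rankdata(diff, axis=1)
    ratio = stats.norm.ppf((ranks - 0.375) / (n_samples + 0.25))

    nlp1 = _regress_rows(p1, g)
    nlp2 = _regress_rows(p2, g)
    nlp3 = _regress_rows(ratio, g)
    gains = nlp3 - np.maximum(nlp1, nlp2)

    crit = pgain_threshold(1)
    k = int((gains > crit).sum())
    frac = k / n_reps
    se = math.sqrt(max(frac * (1 - frac), 1.0 / n_reps) / n_reps)
    return NullCalibration(
        exceedance=frac,
        ci_low=max(0.0, frac - 1.96 * se),
        ci_high=min(1.0, frac + 1.96 * se),
        n_reps=n_reps,
        seed=seed,
    )
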