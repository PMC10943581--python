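"""Variant QC and covariate-adjusted linear-model association testing.

All p-values are carried on the -log10 scale and computed in log space so
that tests remain accurate far beyond the point where a raw p-value would
underflow a double (-log10 p in the thousands is routine for strong QTLs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "AssocResult",
    "QCReport",
    "hwe_exact_pvalue",
    "linear_assoc",
    "neglog10_p_from_t",
    "variant_qc",
]

_LN10 = math.log(10.0)

#: below this two-sided p the direct incomplete-beta evaluation is at risk of
#: underflow and the log-space series takes over
_P_UNDERFLOW_GUARD = 1e-280


@dataclass(frozen=True)
class AssocResult:
    """One trait-variant linear association."""

    trait: str
    variant: str
    n: int
    beta: float
    se: float
    t: float
    neglog10_p: float


@dataclass
class QCReport:
    """Per-filter removal tallies from :func:`variant_qc`."""

    n_samples_in: int = 0
    n_variants_in: int = 0
    samples_removed_mind: int = 0
    variants_removed_geno: int = 0
    variants_removed_maf: int = 0
    variants_removed_mac: int = 0
    variants_removed_hwe: int = 0
    n_samples_out: int = 0
    n_variants_out: int = 0

    @property
    def variants_removed(self) -> int:
        return (
            self.variants_removed_geno
            + self.variants_removed_maf
            + self.variants_removed_mac
            + self.variants_removed_hwe
        )


def neglog10_p_from_t(t: float, df: float) -> float:
    """Two-sided -log10 p for a t statistic, exact deep into the tail.

    For moderate tails the regularized incomplete beta from scipy is used
    directly.  Once the two-sided p would underflow, the same quantity is
    evaluated in log space via the hypergeometric series

        I_x(a, b) = x^a (1-x)^b / (a B(a, b)) * 2F1(1, a+b; a+1; x)

    with a = df/2, b = 1/2, x = df/(df + t^2), which converges quickly
    exactly in the regime where the direct evaluation fails (x away from 1).
    """
    if not np.isfinite(t):
        raise ValueError(f"non-finite t statistic: {t!r}")
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    at = abs(float(t))
    if at == 0.0:
        return 0.0
    if math.isinf(at):
        return math.inf
    x = df / (df + at * at)
    # two-sided p = I_x(df/2, 1/2)
    p2 = special.betainc(df / 2.0, 0.5, x)
    if p2 > _P_UNDERFLOW_GUARD:
        return -math.log10(p2)
    a = df / 2.0
    b = 0.5
    log_pref = (
        a * math.log(x)
        + b * math.log1p(-x)
        - math.log(a)
        - special.betaln(a, b)
    )
    # 2F1(1, a+b; a+1; x) = sum_n prod_{k<n} (a+b+k)/(a+1+k) * x^n
    s = 1.0
    c = 1.0
    n = 0
    while True:
        c *= (a + b + n) / (a + 1.0 + n) * x
        s += c
        n += 1
        if c <= s * 1e-18 or n >= 5_000_000:
            break
    return -(log_pref + math.log(s)) / _LN10


def hwe_exact_pvalue(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg equilibrium test on genotype counts.

    The p-value is the total probability, conditional on the allele counts,
    of all heterozygote counts whose probability does not exceed that of the
    observed count (no mid-p correction).  Probabilities are evaluated with
    log-gamma arithmetic so arbitrarily large samples are handled.
    """
    counts = (n_hom1, n_het, n_hom2)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count in {counts}")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("empty genotype table")
    n_a = 2 * n_hom1 + n_het
    n_b = 2 * n_hom2 + n_het
    n_minor = min(n_a, n_b)
    if n_minor == 0:
        return 1.0

    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # log P(het = h | allele counts) up to the shared normalizing constant
    logp = (
        hets * math.log(2.0)
        - special.gammaln((n_a - hets) / 2.0 + 1.0)
        - special.gammaln(hets + 1.0)
        - special.gammaln((n_b - hets) / 2.0 + 1.0)
    )
    logp -= special.logsumexp(logp)
    obs = logp[(hets == n_het).nonzero()[0][0]]
    # tolerance mirrors plink: include configurations tied with the observed
    mask = logp <= obs + 1e-12
    return float(min(1.0, math.exp(special.logsumexp(logp[mask]))))


def _genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    ok = ~np.isnan(dosages)
    d = dosages[ok]
    return int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum())


def variant_qc(
    geno: pd.DataFrame,
    geno_max_missing: float = 0.1,
    mind_max_missing: float = 0.1,
    maf_min: float = 0.01,
    mac_min: int = 100,
    hwe_p_min: float = 1e-15,
) -> tuple[pd.DataFrame, QCReport]:
    """Sample- then variant-level genotype QC.

    Samples with missing fraction > ``mind_max_missing`` are removed first;
    per-variant statistics (missingness, MAF, MAC, HWE) are then computed on
    the retained samples, and variants failing any filter are dropped.  Each
    removed variant is attributed to the first filter it fails, in the order
    geno > maf > mac > hwe.
    """
    for name, v in (
        ("geno_max_missing", geno_max_missing),
        ("mind_max_missing", mind_max_missing),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError(f"maf_min must be in [0, 0.5], got {maf_min}")

    report = QCReport(n_samples_in=geno.shape[0], n_variants_in=geno.shape[1])
    values = geno.to_numpy(dtype=float)

    sample_miss = np.isnan(values).mean(axis=1)
    keep_samples = sample_miss <= mind_max_missing
    report.samples_removed_mind = int((~keep_samples).sum())
    values = values[keep_samples]
    if values.shape[0] == 0:
        raise ValueError(
            "variant QC removed every sample "
            f"(mind filter dropped {report.samples_removed_mind})"
        )

    keep_variants = []
    for j in range(values.shape[1]):
        col = values[:, j]
        obs = ~np.isnan(col)
        n_obs = int(obs.sum())
        if n_obs == 0 or (1.0 - n_obs / col.size) > geno_max_missing:
            report.variants_removed_geno += 1
            continue
        alt = float(col[obs].sum())
        freq = alt / (2 * n_obs)
        maf = min(freq, 1.0 - freq)
        if maf < maf_min:
            report.variants_removed_maf += 1
            continue
        mac = min(alt, 2 * n_obs - alt)
        if mac < mac_min:
            report.variants_removed_mac += 1
            continue
        if hwe_exact_pvalue(*_genotype_counts(col)) < hwe_p_min:
            report.variants_removed_hwe += 1
            continue
        keep_variants.append(j)

    out = geno.loc[geno.index[keep_samples], geno.columns[keep_variants]]
    report.n_samples_out, report.n_variants_out = out.shape
    if out.shape[1] == 0:
        raise ValueError(
            "variant QC removed every variant: "
            f"geno={report.variants_removed_geno}, "
            f"maf={report.variants_removed_maf}, "
            f"mac={report.variants_removed_mac}, "
            f"hwe={report.variants_removed_hwe}"
        )
    return out, report


def linear_assoc(
    y: pd.Series,
    g: pd.Series,
    covariates: pd.DataFrame | None = None,
    trait: str = "trait",
    variant: str = "variant",
) -> AssocResult:
    """OLS of a phenotype on genotype dosage plus covariates.

    Samples are aligned by id; only complete cases (phenotype, dosage and
    every covariate observed) enter the fit.  The genotype coefficient is
    tested with a two-sided t test on n - k degrees of freedom.
    """
    ids = y.index.intersection(g.index)
    if covariates is not None and len(covariates.columns) > 0:
        ids = ids.intersection(covariates.index)
        cov = covariates.loc[ids].to_numpy(dtype=float)
    else:
        cov = np.empty((len(ids), 0))
    yv = y.loc[ids].to_numpy(dtype=float)
    gv = g.loc[ids].to_numpy(dtype=float)
    ok = ~(np.isnan(yv) | np.isnan(gv))
    if cov.shape[1]:
        ok &= ~np.isnan(cov).any(axis=1)
    yv, gv, cov = yv[ok], gv[ok], cov[ok]
    n = yv.size
    n_cov = cov.shape[1]
    if n < n_cov + 3:
        raise ValueError(
            f"only {n} complete cases for {trait} ~ {variant}; "
            f"need at least {n_cov + 3}"
        )
    if np.ptp(gv) == 0:
        raise ValueError(f"variant {variant} is monomorphic in analysis set")

    X = np.column_stack([np.ones(n), gv, cov])
    k = X.shape[1]
    coef, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ coef
    df = n - k
    rss = float(resid @ resid)
    xtx_inv = np.linalg.pinv(X.T @ X)
    beta = float(coef[1])
    tss = float(((yv - yv.mean()) ** 2).sum())
    if rss <= max(tss, 1.0) * 1e-28:
        # perfect fit: residual variance is numerically zero
        return AssocResult(trait, variant, n, beta, 0.0, math.inf, math.inf)
    sigma2 = rss / df
    se = math.sqrt(sigma2 * xtx_inv[1, 1])
    tstat = beta / se
    return AssocResult(
        trait, variant, n, beta, se, tstat, neglog10_p_from_t(tstat, df)
    )
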