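"""Independent brute-force / high-precision oracles used by the tests.

These deliberately avoid the code paths they check: the t-tail oracle uses
arbitrary-precision numeric integration of the density, the HWE and Fisher
oracles enumerate tables with exact rational arithmetic, and the partial
correlation oracle inverts the sample correlation matrix directly.
"""

from __future__ import annotations

import math
from fractions import Fraction

import mpmath as mp
import numpy as np


def neglog10_p_t_oracle(t: float, df: float, dps: int = 80) -> float:
    """Two-sided -log10 p of a t statistic by high-precision quadrature.

    Uses p = I_x(df/2, 1/2) with x = df / (df + t^2) and evaluates the
    incomplete beta integral under the substitution u = x exp(-w / a),
    which turns it into a smooth integrand with unit exponential decay:

        p = x^a / (a B(a, 1/2)) * int_0^inf e^-w (1 - x e^(-w/a))^(-1/2) dw

    Naive quadrature of the t density fails for large df because the
    density decays by thousands of e-folds across any fixed interval.
    """
    with mp.workdps(dps):
        dfm, tm = mp.mpf(df), mp.mpf(abs(t))
        a = dfm / 2
        b = mp.mpf(1) / 2
        x = dfm / (dfm + tm * tm)
        integrand = lambda w: mp.e ** (-w) * (1 - x * mp.e ** (-w / a)) ** (-b)
        integral = mp.quad(integrand, [0, 1, 10, 100, mp.inf])
        logp = (
            a * mp.log(x) - mp.log(a) - mp.log(mp.beta(a, b))
            + mp.log(integral)
        )
        return float(-logp / mp.log(10))


def neglog10_p_normal_oracle(z: float, dps: int = 60) -> float:
    """Two-sided -log10 p of a standard normal deviate."""
    with mp.workdps(dps):
        p = 2 * mp.ncdf(-mp.mpf(abs(z)))
        return float(-mp.log10(p))


def hwe_weights(n_a: int, n_b: int) -> dict[int, int]:
    """Exact integer weights of each heterozygote count given allele counts.

    weight(h) is proportional to the conditional probability of observing h
    heterozygotes: 2^h * n! / (hom1! * h! * hom2!).
    """
    m = min(n_a, n_b)
    n = (n_a + n_b) // 2
    weights: dict[int, int] = {}
    for h in range(m % 2, m + 1, 2):
        a = (n_a - h) // 2
        b = (n_b - h) // 2
        weights[h] = (
            2**h * math.factorial(n)
            // (math.factorial(a) * math.factorial(h) * math.factorial(b))
        )
    return weights


def hwe_exact_oracle(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """HWE exact p by full enumeration with exact integer arithmetic."""
    n_a = 2 * n_hom1 + n_het
    n_b = 2 * n_hom2 + n_het
    if min(n_a, n_b) == 0:
        return 1.0
    weights = hwe_weights(n_a, n_b)
    obs = weights[n_het]
    return float(
        Fraction(sum(w for w in weights.values() if w <= obs),
                 sum(weights.values()))
    )


def fisher_exact_oracle(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """(one-sided greater, two-sided) Fisher p by hypergeometric enumeration.

    Table weights are the exact integers C(row1, x) * C(n - row1, col1 - x).
    """
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    weights = {
        x: math.comb(row1, x) * math.comb(n - row1, col1 - x)
        for x in range(lo, hi + 1)
    }
    total = sum(weights.values())
    obs = weights[a]
    p_greater = Fraction(sum(w for x, w in weights.items() if x >= a), total)
    p_two = Fraction(sum(w for w in weights.values() if w <= obs), total)
    return float(p_greater), float(p_two)


def pcor_direct_oracle(x: np.ndarray) -> np.ndarray:
    """Partial correlations via direct inversion of the sample correlation."""
    r = np.corrcoef(x, rowvar=False)
    omega = np.linalg.inv(r)
    d = np.sqrt(np.diag(omega))
    pc = -omega / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pc
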