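import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ratioqtl.assoc import (
    hwe_exact_pvalue,
    linear_assoc,
    neglog10_p_from_t,
    variant_qc,
)

from .oracles import hwe_exact_oracle, neglog10_p_t_oracle


class TestNeglog10PFromT:
    def test_t_zero_gives_zero(self):
        assert neglog10_p_from_t(0.0, 5) == 0.0
        assert neglog10_p_from_t(0.0, 40000) == 0.0

    def test_nominal_value(self):
        # t = 1.96, large df: p ~ 0.05, -log10 p ~ 1.301
        assert neglog10_p_from_t(1.96, 10_000) == pytest.approx(
            neglog10_p_t_oracle(1.96, 10_000), rel=1e-9
        )
        assert neglog10_p_from_t(1.96, 10_000) == pytest.approx(1.301, abs=2e-3)

    def test_extreme_tail_matches_oracle(self):
        # -log10 p in the thousands
        val = neglog10_p_from_t(130.0, 40_000)
        assert val > 3000
        assert val == pytest.approx(neglog10_p_t_oracle(130.0, 40_000), rel=1e-6)

    @pytest.mark.parametrize("t", [0.1, 2.0, 9.0, 40.0, 130.0])
    @pytest.mark.parametrize("df", [10, 345, 40_000])
    def test_oracle_grid(self, t, df):
        assert neglog10_p_from_t(t, df) == pytest.approx(
            neglog10_p_t_oracle(t, df), rel=1e-6
        )

    def test_agrees_with_naive_where_no_underflow(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        for _ in range(50):
            t = float(rng.uniform(0.01, 25))
            df = int(rng.integers(3, 5000))
            naive = 2 * stats.t.sf(t, df)
            if naive > 1e-300:
                assert neglog10_p_from_t(t, df) == pytest.approx(
                    -math.log10(naive), rel=1e-9
                )

    def test_monotone_in_abs_t(self):
        ts = np.concatenate([np.linspace(0.01, 50, 200), [100, 500, 3000]])
        for df in (5, 1000):
            vals = [neglog10_p_from_t(t, df) for t in ts]
            assert np.all(np.diff(vals) > 0)

    def test_sign_symmetric(self):
        assert neglog10_p_from_t(-7.5, 60) == neglog10_p_from_t(7.5, 60)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            neglog10_p_from_t(float("nan"), 10)
        with pytest.raises(ValueError):
            neglog10_p_from_t(1.0, 0.5)


class TestHweExact:
    def test_balanced_table_is_probable(self):
        p = hwe_exact_pvalue(25, 50, 25)
        assert p == pytest.approx(hwe_exact_oracle(25, 50, 25), rel=1e-10)
        assert p > 0.5

    def test_monomorphic(self):
        assert hwe_exact_pvalue(100, 0, 0) == 1.0
        assert hwe_exact_pvalue(0, 0, 7) == 1.0

    def test_no_hets_extreme(self):
        p = hwe_exact_pvalue(50, 0, 50)
        assert p < 1e-15
        assert p == pytest.approx(hwe_exact_oracle(50, 0, 50), rel=1e-9)

    @given(
        st.integers(0, 20), st.integers(0, 20), st.integers(0, 20)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, a, h, b):
        if a + h + b == 0:
            return
        assert hwe_exact_pvalue(a, h, b) == pytest.approx(
            hwe_exact_oracle(a, h, b), rel=1e-9, abs=1e-300
        )

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            hwe_exact_pvalue(-1, 2, 3)
        with pytest.raises(ValueError):
            hwe_exact_pvalue(0, 0, 0)


def _geno_frame(cols: dict[str, list[float]]) -> pd.DataFrame:
    n = len(next(iter(cols.values())))
    return pd.DataFrame(cols, index=[f"S{i}" for i in range(n)], dtype=float)


class TestVariantQC:
    def test_clean_matrix_untouched(self):
        rng = np.random.default_rng(1)
        g = _geno_frame({"v1": rng.binomial(2, 0.3, 1000).tolist()})
        out, report = variant_qc(g)
        assert out.shape == (1000, 1)
        assert report.variants_removed == 0
        assert report.samples_removed_mind == 0

    def test_rare_variant_removed_by_maf(self):
        rng = np.random.default_rng(2)
        g = _geno_frame(
            {
                "common": rng.binomial(2, 0.3, 2000).tolist(),
                "rare": rng.binomial(2, 0.005, 2000).tolist(),
            }
        )
        out, report = variant_qc(g, mac_min=10)
        assert list(out.columns) == ["common"]
        assert report.variants_removed_maf == 1

    def test_hwe_violation_removed(self):
        # (AA, Aa, aa) = (50, 0, 50): enumeration oracle p << 1e-15
        assert hwe_exact_oracle(50, 0, 50) < 1e-15
        g = _geno_frame({"bad": [2.0] * 50 + [0.0] * 50})
        with pytest.raises(ValueError, match="hwe=1"):
            variant_qc(g, maf_min=0.01, mac_min=10)

    def test_mac_filter(self):
        g = _geno_frame({"v": [1.0] * 30 + [0.0] * 70})
        with pytest.raises(ValueError, match="mac=1"):
            variant_qc(g, maf_min=0.01, mac_min=100, hwe_p_min=0.0)

    def test_mind_before_variant_filters(self):
        # sample S0 is 100% missing; after dropping it v1 is complete
        g = _geno_frame({"v1": [np.nan] + [1.0, 0.0] * 50})
        g.iloc[0, 0] = np.nan
        out, report = variant_qc(g, maf_min=0.0, mac_min=0, hwe_p_min=0.0)
        assert report.samples_removed_mind == 1
        assert out.shape == (100, 1)

    def test_report_counts_sum(self):
        rng = np.random.default_rng(3)
        g = _geno_frame(
            {
                "ok": rng.binomial(2, 0.4, 500).tolist(),
                "rare": rng.binomial(2, 0.002, 500).tolist(),
                "lowmac": rng.binomial(2, 0.012, 500).tolist(),
            }
        )
        out, report = variant_qc(g, mac_min=50)
        assert report.n_variants_in == report.variants_removed + out.shape[1]


class TestLinearAssoc:
    def test_recovers_known_slope(self):
        rng = np.random.default_rng(4)
        n = 5000
        g = pd.Series(rng.binomial(2, 0.3, n).astype(float),
                      index=[f"S{i}" for i in range(n)])
        y = 0.5 * g + pd.Series(rng.normal(size=n), index=g.index)
        res = linear_assoc(y, g)
        assert res.beta == pytest.approx(0.5, abs=3 * res.se)
        assert res.n == n

    def test_perfect_fit_sentinel(self):
        g = pd.Series([0.0, 1.0, 2.0] * 34, index=range(102))
        res = linear_assoc(g.astype(float), g)
        assert math.isinf(res.neglog10_p)
        assert res.se == 0.0

    def test_null_uniform_pvalues(self):
        rng = np.random.default_rng(5)
        n, reps = 300, 2000
        hits = 0
        for _ in range(reps):
            g = pd.Series(rng.binomial(2, 0.3, n).astype(float))
            y = pd.Series(rng.normal(size=n))
            res = linear_assoc(y, g)
            hits += res.neglog10_p > -math.log10(0.05)
        frac = hits / reps
        se = math.sqrt(0.05 * 0.95 / reps)
        assert abs(frac - 0.05) < 4 * se

    def test_negated_phenotype_flips_beta_only(self):
        rng = np.random.default_rng(6)
        n = 500
        g = pd.Series(rng.binomial(2, 0.25, n).astype(float))
        cov = pd.DataFrame({"age": rng.uniform(40, 70, n)})
        y = pd.Series(0.3 * g + rng.normal(size=n))
        r1 = linear_assoc(y, g, cov)
        r2 = linear_assoc(-y, g, cov)
        assert r2.beta == pytest.approx(-r1.beta, rel=1e-12)
        assert r2.neglog10_p == pytest.approx(r1.neglog10_p, rel=1e-12)

    def test_monomorphic_raises(self):
        g = pd.Series([1.0] * 50)
        y = pd.Series(np.random.default_rng(7).normal(size=50))
        with pytest.raises(ValueError, match="monomorphic"):
            linear_assoc(y, g)

    def test_complete_case_alignment_by_id(self):
        # ids intersect out of order; missing values dropped per test
        g = pd.Series([0.0, 1.0, 2.0, 1.0, 0.0, 2.0, 1.0, 0.0, 1.0, 2.0],
                      index=[f"S{i}" for i in range(10)])
        y = pd.Series(np.arange(10, dtype=float),
                      index=[f"S{i}" for i in reversed(range(10))])
        y.iloc[0] = np.nan
        res = linear_assoc(y, g)
        assert res.n == 9
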