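import numpy as np
import pandas as pd
import pytest

from ratioqtl.assoc import linear_assoc
from ratioqtl.preprocess import make_ratio_phenotype
from ratioqtl.simulate import (
    ProteinDef,
    SCENARIOS,
    SyntheticModelSpec,
    VariantDef,
    generate_cohort,
    scenario_preset,
    spec_from_dict,
    spec_to_dict,
)


def _null_spec(n=2000, seed=0, missing_rate=0.0):
    return SyntheticModelSpec(
        n_samples=n,
        n_discovery=n,
        variants=[VariantDef("v1", "1", 100, 0.3)],
        proteins=[
            ProteinDef("P1", "1", 10, 20),
            ProteinDef("P2", "2", 10, 20),
        ],
        alpha=np.array([1.5, -2.0]),
        beta=np.zeros((2, 1)),
        gamma=np.zeros((2, 0)),
        n_factors=0,
        epsilon_sd=np.ones(2),
        missing_rate=missing_rate,
        seed=seed,
    )


class TestGenerateCohort:
    def test_null_model_moments(self):
        c = generate_cohort(_null_spec(n=4000, seed=1))
        tol = 3.0 / np.sqrt(4000)
        assert c.proteins["P1"].mean() == pytest.approx(1.5, abs=tol)
        assert c.proteins["P2"].mean() == pytest.approx(-2.0, abs=tol)
        assert c.proteins["P1"].std() == pytest.approx(1.0, abs=0.06)

    def test_genotype_frequency_matches_maf(self):
        c = generate_cohort(_null_spec(n=10_000, seed=2))
        g = c.genotypes["v1"]
        assert set(np.unique(g)) <= {0.0, 1.0, 2.0}
        freq = g.mean() / 2
        assert freq == pytest.approx(0.3, abs=3 * np.sqrt(0.3 * 0.7 / 20_000))

    def test_ratio_slope_recovers_beta_difference(self):
        # beta1 - beta2 = 0.6; fit on n = 10,000
        spec = scenario_preset("opposite_beta", n_samples=10_000, seed=3)
        c = generate_cohort(spec)
        diff = c.proteins["P1"] - c.proteins["P2"]
        res = linear_assoc(diff, c.genotypes["v1"])
        assert abs(res.beta - 0.6) < 1.96 * res.se

    def test_deterministic_given_seed(self):
        a = generate_cohort(_null_spec(seed=4, missing_rate=0.1))
        b = generate_cohort(_null_spec(seed=4, missing_rate=0.1))
        pd.testing.assert_frame_equal(a.proteins, b.proteins)
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)

    def test_no_missing_when_rate_zero(self):
        c = generate_cohort(_null_spec())
        assert not c.proteins.isna().any().any()

    def test_missing_rate_applied(self):
        c = generate_cohort(_null_spec(n=5000, missing_rate=0.2, seed=5))
        frac = c.proteins.isna().to_numpy().mean()
        assert frac == pytest.approx(0.2, abs=0.02)

    def test_cohort_split_sizes(self):
        spec = scenario_preset("null", n_samples=100, n_discovery=70)
        c = generate_cohort(spec)
        assert len(c.discovery_ids) == 70
        assert len(c.replication_ids) == 30

    def test_covariate_effects_propagate(self):
        spec = _null_spec(n=20_000, seed=6)
        spec.covariate_effects = np.array(
            [[0.1, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, 0.0]]
        )
        spec.validate()
        c = generate_cohort(spec)
        slope = np.polyfit(c.covariates["age"], c.proteins["P1"], 1)[0]
        assert slope == pytest.approx(0.1, abs=0.02)

    def test_shape_mismatch_names_field(self):
        spec = _null_spec()
        spec.beta = np.zeros((3, 1))
        with pytest.raises(ValueError, match="beta"):
            spec.validate()
        spec = _null_spec()
        spec.alpha = np.zeros(5)
        with pytest.raises(ValueError, match="alpha"):
            spec.validate()

    def test_rejects_invalid_scalars(self):
        with pytest.raises(ValueError, match="n_samples"):
            _s = _null_spec(n=0)
        spec = _null_spec()
        spec.missing_rate = 1.0
        with pytest.raises(ValueError, match="missing_rate"):
            spec.validate()
        spec = _null_spec()
        spec.epsilon_sd = np.array([1.0, 0.0])
        with pytest.raises(ValueError, match="epsilon_sd"):
            spec.validate()


class TestScenarioPreset:
    def test_null_all_zero(self):
        spec = scenario_preset("null")
        assert not spec.beta.any()
        assert not spec.gamma.any()

    def test_opposite_beta_signs(self):
        spec = scenario_preset("opposite_beta")
        b1, b2 = spec.beta[:, 0]
        assert b1 != 0 and b2 != 0
        assert np.sign(b1) == -np.sign(b2)
        assert not spec.gamma.any()

    def test_single_beta_shared_w(self):
        spec = scenario_preset("single_beta_shared_W")
        assert spec.beta[1, 0] == 0 and spec.beta[0, 0] != 0
        assert spec.gamma[0, 0] == spec.gamma[1, 0] != 0

    def test_shared_beta_shared_w_cancels(self):
        spec = scenario_preset("shared_beta_shared_W")
        assert spec.beta[0, 0] == spec.beta[1, 0] != 0
        assert spec.gamma[0, 0] == spec.gamma[1, 0] != 0

    def test_unknown_name_lists_valid(self):
        with pytest.raises(ValueError) as exc:
            scenario_preset("bogus")
        for name in SCENARIOS:
            assert name in str(exc.value)

    def test_shared_scenario_ratio_is_null(self):
        # ratio p-values uniform under full cancellation (KS test)
        from scipy import stats

        pvals = []
        for seed in range(150):
            spec = scenario_preset(
                "shared_beta_shared_W", n_samples=400, seed=seed
            )
            c = generate_cohort(spec)
            pheno = make_ratio_phenotype(c.proteins, ("P1", "P2"))
            res = linear_assoc(pheno, c.genotypes["v1"])
            pvals.append(10 ** (-res.neglog10_p))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_amplification_under_opposite_beta(self):
        from ratioqtl.preprocess import inverse_normal_transform

        wins = 0
        for seed in range(40):
            spec = scenario_preset("opposite_beta", n_samples=800, seed=seed)
            c = generate_cohort(spec)
            g = c.genotypes["v1"]
            p1 = linear_assoc(
                inverse_normal_transform(c.proteins["P1"]), g
            ).neglog10_p
            p2 = linear_assoc(
                inverse_normal_transform(c.proteins["P2"]), g
            ).neglog10_p
            p3 = linear_assoc(
                make_ratio_phenotype(c.proteins, ("P1", "P2")), g
            ).neglog10_p
            wins += p3 > max(p1, p2)
        assert wins > 30  # median ratio signal beats both singles


class TestSpecRoundTrip:
    def test_dict_round_trip(self):
        spec = scenario_preset("single_beta_shared_W", n_samples=123, seed=9)
        back = spec_from_dict(spec_to_dict(spec))
        assert spec_to_dict(back) == spec_to_dict(spec)

    def test_round_trip_generates_identical_cohort(self):
        spec = scenario_preset("opposite_beta", n_samples=50, seed=10)
        back = spec_from_dict(spec_to_dict(spec))
        a, b = generate_cohort(spec), generate_cohort(back)
        pd.testing.assert_frame_equal(a.proteins, b.proteins)
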