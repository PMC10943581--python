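"""Synthetic cohort generation under an additive log-linear protein model.

Each log-scale protein level is generated as

    log(P_i) = alpha_i + sum_v beta_iv * SNP_v + sum_f gamma_if * W_f
               + covariate terms + eps_i

with biallelic genotypes drawn Binomial(2, MAF) under Hardy-Weinberg,
shared latent factors W ~ N(0, 1), and Gaussian residuals.  A cohort label
splits samples into discovery and replication sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticCohort",
    "SyntheticModelSpec",
    "VariantDef",
    "ProteinDef",
    "generate_cohort",
    "scenario_preset",
    "spec_from_dict",
    "spec_to_dict",
    "write_cohort",
    "SCENARIOS",
]

COVARIATE_NAMES = ("age", "sex", "PC1", "PC2", "PC3")


@dataclass(frozen=True)
class VariantDef:
    id: str
    chrom: str
    pos: int
    maf: float
    effect_allele: str = "A"
    other_allele: str = "G"


@dataclass(frozen=True)
class ProteinDef:
    id: str
    gene_chrom: str
    gene_start: int
    gene_end: int


@dataclass
class SyntheticModelSpec:
    """Full parameterization of the generative model.

    ``beta`` is (n_proteins x n_variants), ``gamma`` (n_proteins x
    n_factors), ``covariate_effects`` optionally (n_proteins x 5) loadings
    on (age, sex, PC1, PC2, PC3).
    """

    n_samples: int
    n_discovery: int
    variants: list[VariantDef]
    proteins: list[ProteinDef]
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    n_factors: int
    epsilon_sd: np.ndarray
    missing_rate: float = 0.0
    covariate_effects: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.epsilon_sd = np.asarray(self.epsilon_sd, dtype=float)
        if self.covariate_effects is not None:
            self.covariate_effects = np.asarray(
                self.covariate_effects, dtype=float
            )
        self.validate()

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError(f"n_samples must be positive, got {self.n_samples}")
        if not 0 <= self.n_discovery <= self.n_samples:
            raise ValueError(
                f"n_discovery must be in [0, n_samples], got {self.n_discovery}"
            )
        p, v, f = self.n_proteins, self.n_variants, self.n_factors
        if self.alpha.shape != (p,):
            raise ValueError(f"alpha has shape {self.alpha.shape}, expected ({p},)")
        if self.beta.shape != (p, v):
            raise ValueError(f"beta has shape {self.beta.shape}, expected ({p}, {v})")
        if self.gamma.shape != (p, f):
            raise ValueError(f"gamma has shape {self.gamma.shape}, expected ({p}, {f})")
        if self.epsilon_sd.shape != (p,):
            raise ValueError(
                f"epsilon_sd has shape {self.epsilon_sd.shape}, expected ({p},)"
            )
        if (self.epsilon_sd <= 0).any():
            raise ValueError("epsilon_sd entries must be > 0")
        for var in self.variants:
            if not 0.0 < var.maf <= 0.5:
                raise ValueError(f"maf of {var.id} must be in (0, 0.5], got {var.maf}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(
                f"missing_rate must be in [0, 1), got {self.missing_rate}"
            )
        if self.covariate_effects is not None and self.covariate_effects.shape != (
            p,
            len(COVARIATE_NAMES),
        ):
            raise ValueError(
                "covariate_effects has shape "
                f"{self.covariate_effects.shape}, expected ({p}, {len(COVARIATE_NAMES)})"
            )


@dataclass
class SyntheticCohort:
    """A simulated cohort plus the spec that generated it."""

    genotypes: pd.DataFrame
    proteins: pd.DataFrame
    covariates: pd.DataFrame
    cohort: pd.Series
    spec: SyntheticModelSpec

    @property
    def discovery_ids(self) -> pd.Index:
        return self.cohort.index[self.cohort == "discovery"]

    @property
    def replication_ids(self) -> pd.Index:
        return self.cohort.index[self.cohort == "replication"]


def generate_cohort(spec: SyntheticModelSpec) -> SyntheticCohort:
    """Draw one cohort from the generative model, deterministic in the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    sample_ids = pd.Index([f"S{i:06d}" for i in range(n)], name="sample_id")

    mafs = np.array([v.maf for v in spec.variants])
    geno = rng.binomial(2, mafs, size=(n, spec.n_variants)).astype(float)
    w = rng.standard_normal((n, spec.n_factors))
    age = rng.uniform(40.0, 70.0, size=n)
    sex = rng.binomial(1, 0.5, size=n).astype(float)
    pcs = rng.standard_normal((n, 3))
    cov = np.column_stack([age, sex, pcs])
    eps = rng.standard_normal((n, spec.n_proteins)) * spec.epsilon_sd

    prot = spec.alpha + geno @ spec.beta.T + w @ spec.gamma.T + eps
    if spec.covariate_effects is not None:
        prot = prot + cov @ spec.covariate_effects.T
    if spec.missing_rate > 0:
        mask = rng.random(prot.shape) < spec.missing_rate
        prot = np.where(mask, np.nan, prot)

    labels = np.where(
        np.arange(n) < spec.n_discovery, "discovery", "replication"
    )
    return SyntheticCohort(
        genotypes=pd.DataFrame(
            geno, index=sample_ids, columns=[v.id for v in spec.variants]
        ),
        proteins=pd.DataFrame(
            prot, index=sample_ids, columns=[p.id for p in spec.proteins]
        ),
        covariates=pd.DataFrame(
            cov, index=sample_ids, columns=list(COVARIATE_NAMES)
        ),
        cohort=pd.Series(labels, index=sample_ids, name="cohort"),
        spec=spec,
    )


def _two_protein_spec(
    beta1: float,
    beta2: float,
    gamma1: float,
    gamma2: float,
    n_samples: int,
    n_discovery: int,
    maf: float,
    seed: int,
) -> SyntheticModelSpec:
    return SyntheticModelSpec(
        n_samples=n_samples,
        n_discovery=n_discovery,
        variants=[VariantDef("v1", "1", 1_000_000, maf)],
        proteins=[
            ProteinDef("P1", "1", 900_000, 950_000),
            ProteinDef("P2", "2", 5_000_000, 5_050_000),
        ],
        alpha=np.zeros(2),
        beta=np.array([[beta1], [beta2]]),
        gamma=np.array([[gamma1], [gamma2]]),
        n_factors=1,
        epsilon_sd=np.ones(2),
        seed=seed,
    )


SCENARIOS = {
    "opposite_beta": dict(beta1=0.3, beta2=-0.3, gamma1=0.0, gamma2=0.0),
    "single_beta_shared_W": dict(beta1=0.5, beta2=0.0, gamma1=1.0, gamma2=1.0),
    "shared_beta_shared_W": dict(beta1=0.3, beta2=0.3, gamma1=1.0, gamma2=1.0),
    "null": dict(beta1=0.0, beta2=0.0, gamma1=0.0, gamma2=0.0),
}


def scenario_preset(
    name: str,
    n_samples: int = 5000,
    n_discovery: int | None = None,
    maf: float = 0.3,
    seed: int = 0,
) -> SyntheticModelSpec:
    """Two-protein, one-variant spec for a canonical p-gain scenario.

    ``opposite_beta``: genetic effects of opposite sign, no shared factor —
    the ratio amplifies the signal.  ``single_beta_shared_W``: one protein
    carries the genetic effect, both share a latent factor that the ratio
    removes.  ``shared_beta_shared_W``: both the genetic effect and the
    factor cancel, so the ratio is null.  ``null``: no effects at all.
    """
    if name not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {name!r}; valid: {sorted(SCENARIOS)}"
        )
    if n_discovery is None:
        n_discovery = n_samples
    return _two_protein_spec(
        n_samples=n_samples,
        n_discovery=n_discovery,
        maf=maf,
        seed=seed,
        **SCENARIOS[name],
    )


def spec_to_dict(spec: SyntheticModelSpec) -> dict:
    """Plain-dict (YAML-safe) form of a model spec."""
    return {
        "n_samples": spec.n_samples,
        "n_discovery": spec.n_discovery,
        "variants": [
            {
                "id": v.id,
                "chrom": v.chrom,
                "pos": v.pos,
                "maf": v.maf,
                "effect_allele": v.effect_allele,
                "other_allele": v.other_allele,
            }
            for v in spec.variants
        ],
        "proteins": [
            {
                "id": p.id,
                "gene_chrom": p.gene_chrom,
                "gene_start": p.gene_start,
                "gene_end": p.gene_end,
            }
            for p in spec.proteins
        ],
        "alpha": spec.alpha.tolist(),
        "beta": spec.beta.tolist(),
        "gamma": spec.gamma.tolist(),
        "n_factors": spec.n_factors,
        "epsilon_sd": spec.epsilon_sd.tolist(),
        "missing_rate": spec.missing_rate,
        "covariate_effects": (
            None
            if spec.covariate_effects is None
            else spec.covariate_effects.tolist()
        ),
        "seed": spec.seed,
    }


def spec_from_dict(data: dict) -> SyntheticModelSpec:
    cov = data.get("covariate_effects")
    return SyntheticModelSpec(
        n_samples=int(data["n_samples"]),
        n_discovery=int(data["n_discovery"]),
        variants=[VariantDef(**v) for v in data["variants"]],
        proteins=[ProteinDef(**p) for p in data["proteins"]],
        alpha=np.asarray(data["alpha"], dtype=float),
        beta=np.asarray(data["beta"], dtype=float),
        gamma=np.asarray(data["gamma"], dtype=float),
        n_factors=int(data["n_factors"]),
        epsilon_sd=np.asarray(data["epsilon_sd"], dtype=float),
        missing_rate=float(data.get("missing_rate", 0.0)),
        covariate_effects=None if cov is None else np.asarray(cov, dtype=float),
        seed=int(data.get("seed", 0)),
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write a cohort's tables plus the generating truth to a directory.

    Returns a mapping of logical names to the paths written.
    """
    import pathlib

    import yaml

    from . import io as _io

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": outdir / "proteins.tsv",
        "genotypes": outdir / "genotypes.raw",
        "variants": outdir / "variants.tsv",
        "genes": outdir / "genes.tsv",
        "covariates": outdir / "covariates.tsv",
        "cohorts": outdir / "cohorts.tsv",
        "truth": outdir / "truth.yaml",
    }
    _io.write_protein_matrix(cohort.proteins, paths["proteins"])
    alleles = {v.id: v.effect_allele for v in cohort.spec.variants}
    _io.write_genotypes_raw(cohort.genotypes, alleles, paths["genotypes"])
    variant_df = pd.DataFrame(
        {
            "chrom": [v.chrom for v in cohort.spec.variants],
            "pos": [v.pos for v in cohort.spec.variants],
            "a1": [v.effect_allele for v in cohort.spec.variants],
            "a2": [v.other_allele for v in cohort.spec.variants],
        },
        index=pd.Index([v.id for v in cohort.spec.variants], name="id"),
    )
    _io.write_variant_info(variant_df, paths["variants"])
    gene_df = pd.DataFrame(
        {
            "chrom": [p.gene_chrom for p in cohort.spec.proteins],
            "start": [p.gene_start for p in cohort.spec.proteins],
            "end": [p.gene_end for p in cohort.spec.proteins],
        },
        index=pd.Index([p.id for p in cohort.spec.proteins], name="protein"),
    )
    _io.write_gene_table(gene_df, paths["genes"])
    _io.write_covariates(cohort.covariates, paths["covariates"])
    cohort.cohort.to_frame().to_csv(
        paths["cohorts"], sep="\t", index_label="sample_id"
    )
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(spec_to_dict(cohort.spec), fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
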