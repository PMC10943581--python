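from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ratioqtl.simulate import (
    ProteinDef,
    SyntheticModelSpec,
    VariantDef,
    generate_cohort,
    scenario_preset,
)


@pytest.fixture(scope="session")
def opposite_beta_cohort():
    """opposite_beta scenario, 6,000 samples (5,000 discovery)."""
    spec = scenario_preset(
        "opposite_beta", n_samples=6000, n_discovery=5000, seed=11
    )
    return generate_cohort(spec)


@pytest.fixture()
def toy_matrix_10x4() -> pd.DataFrame:
    """10 samples x 4 proteins; sample S3 is 3/4 missing and, once S3 is
    removed, protein B is 3/9 missing (above a 0.2 threshold)."""
    rng = np.random.default_rng(7)
    m = pd.DataFrame(
        rng.normal(size=(10, 4)),
        index=[f"S{i}" for i in range(10)],
        columns=list("ABCD"),
    )
    m.loc["S3", ["A", "B", "C"]] = np.nan
    m.loc[["S5", "S8", "S9"], "B"] = np.nan  # B: 3/9 missing after dropping S3
    return m


@pytest.fixture(scope="session")
def multi_signal_spec() -> SyntheticModelSpec:
    """10 proteins, 3 variants; v1 hits P0/P1 with opposite signs, v2 hits
    P2 only while P2/P3 share a latent factor, v3 is null."""
    n_prot, n_var = 10, 3
    beta = np.zeros((n_prot, n_var))
    beta[0, 0], beta[1, 0] = 0.4, -0.4
    beta[2, 1] = 0.5
    gamma = np.zeros((n_prot, 1))
    gamma[2, 0] = gamma[3, 0] = 1.2
    return SyntheticModelSpec(
        n_samples=4000,
        n_discovery=3000,
        variants=[
            VariantDef(f"v{i+1}", str(i + 1), 10_000_000 * (i + 1), 0.3)
            for i in range(n_var)
        ],
        proteins=[
            ProteinDef(f"P{i}", str(i % 5 + 1), 1_000_000 * (i + 1),
                       1_000_000 * (i + 1) + 50_000)
            for i in range(n_prot)
        ],
        alpha=np.zeros(n_prot),
        beta=beta,
        gamma=gamma,
        n_factors=1,
        epsilon_sd=np.ones(n_prot),
        seed=23,
    )
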