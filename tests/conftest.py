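import numpy as np
import pandas as pd
import pytest

from hybridtrio import NoiseParams, SimConfig, run_trio, simulate_trio


def make_tmm_fixture(n: int = 200, seed: int = 777) -> pd.DataFrame:
    """Deterministic 200-gene, 3-sample NB count matrix with sample s3
    inflated 4x on a random 30% of genes (a composition shift that TMM
    must correct)."""
    rng = np.random.default_rng(seed)
    mu = 2 ** rng.normal(6, 1.5, n)
    phi = 0.1
    r = 1 / phi
    base = np.column_stack(
        [rng.negative_binomial(r, r / (r + mu)) for _ in range(3)]
    ).astype(float)
    inflated = rng.random(n) < 0.3
    base[inflated, 2] *= 4.0
    return pd.DataFrame(
        base, columns=["s1", "s2", "s3"], index=[f"g{i:03d}" for i in range(n)]
    )


#: TMM factors computed on make_tmm_fixture() by an independent reference
#: implementation (edgeR 4.0.16 calcNormFactors, method="TMM")
EDGER_TMM_FACTORS = {
    "s1": 1.1368226063,
    "s2": 1.1403953795,
    "s3": 0.7713506500,
}


@pytest.fixture(scope="session")
def tmm_fixture_counts() -> pd.DataFrame:
    return make_tmm_fixture()


@pytest.fixture(scope="session")
def recovery_run():
    """The reference recovery scenario, run once per session: 5,000 genes,
    70% conserved / 6% each other mode, parental lfc 2, dominance delta 2,
    phi 0.05, 5e6-read libraries, seed 1."""
    config = SimConfig(seed=1)
    table, truth = simulate_trio(config)
    result = run_trio(table, params=NoiseParams(seed=1))
    return config, table, truth, result
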