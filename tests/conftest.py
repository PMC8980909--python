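import numpy as np
import pytest

from divage import PhenotypeSpec, SimulationConfig, simulate_cohort
from divage.grs import demo_weights


@pytest.fixture(scope="session")
def weights23():
    """Synthetic 23-variant weight panel (2 variants in the APOE region)."""
    return demo_weights()


@pytest.fixture(scope="session")
def divergent_cohort():
    """Mid-sized cohort with a strong true divergence at age 50."""
    spec = PhenotypeSpec(
        name="cognition",
        base_coefs=(0.0, -0.25, -0.05),
        true_threshold_age=50.0,
        divergence_coef=-0.2,
        residual_sd=1.0,
        covariate_effects={"sex": 0.1},
    )
    config = SimulationConfig(
        n_participants=8000, seed=11, phenotype_specs=(spec,), n_centers=3
    )
    return simulate_cohort(config), spec, config


@pytest.fixture()
def toy_cohort():
    """Small cohort for closed-form / oracle comparisons."""
    spec = PhenotypeSpec(
        name="score", base_coefs=(1.0, -0.3, -0.05), residual_sd=0.8
    )
    config = SimulationConfig(
        n_participants=200, seed=5, phenotype_specs=(spec,), n_centers=2, n_pcs=2
    )
    return simulate_cohort(config)


def normal_equation_beta(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Brute-force (X'X)^-1 X'y oracle used across the suite."""
    return np.linalg.inv(X.T @ X) @ (X.T @ y)
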