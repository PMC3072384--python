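import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from breedtrace import TreeConfig, filter_missing, loocv, simulate_dataset, two_level_spec

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

# Fixed study conditions of the end-to-end experiment: six breeds in a
# two-level hierarchy (between-group F_ST 0.15, within-group 0.05), 40
# individuals per breed, 2,000 base SNPs, 5% missing calls, one fifth of
# the SNPs duplicated twice with 5% per-entry corruption.
STUDY_SEED = 1


def study_spec(seed: int = STUDY_SEED):
    return two_level_spec(seed=seed)


@pytest.fixture(scope="session")
def small_sim():
    """Reduced-scale version of the study conditions for cheap unit tests."""
    gm, truth = simulate_dataset(two_level_spec(seed=11, n_per_breed=20, n_snps=500))
    return gm, truth


@pytest.fixture(scope="session")
def study_sim():
    gm, truth = simulate_dataset(study_spec())
    return gm, truth


@pytest.fixture(scope="session")
def study_loocv(study_sim):
    """Full leave-one-out experiment under the study conditions (all tiers)."""
    gm, _ = study_sim
    gm = filter_missing(gm)
    return loocv(gm, TreeConfig(seed=STUDY_SEED), modes=("full", "P1", "P2", "P3"))


def rng_matrix(seed: int, n: int = 20, m: int = 50) -> np.ndarray:
    """Random centred matrix used by the score/CSSP checks."""
    X = np.random.default_rng(seed).normal(size=(n, m))
    return X - X.mean(axis=0)
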