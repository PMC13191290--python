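import numpy as np
import pytest

from kre.config import PipelineConfig
from kre.simulate import CohortConfig, simulate_cohort


def small_cohort_config(seed: int = 11, noise_sigma: float = 0.1) -> CohortConfig:
    """A desk-scale cohort small enough for per-test pipeline runs."""
    return CohortConfig(
        n_elements=400,
        n_genes=80,
        n_features=40,
        n_decoy_features=2,
        planted_features=[(i, 0.60, 0.16) for i in range(6)],
        egr1_planted_features=[(i, 0.65, 0.12) for i in range(6, 12)],
        noise_sigma=noise_sigma,
        seed=seed,
    )


def small_pipeline_config(workdir, seed: int = 11, noise_sigma: float = 0.1) -> PipelineConfig:
    cfg = PipelineConfig(
        workdir=str(workdir),
        seed=seed,
        cohort=small_cohort_config(seed=seed, noise_sigma=noise_sigma),
        hyperparams={"n_estimators": 100},
    )
    cfg.thresholds.min_peaks = 10
    return cfg


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """(outdir, truth) for a noisy small cohort shared across tests."""
    outdir = tmp_path_factory.mktemp("cohort_noisy")
    truth = simulate_cohort(small_cohort_config(), outdir)
    return outdir, truth


@pytest.fixture(scope="session")
def noiseless_cohort(tmp_path_factory):
    """(outdir, truth) for an exactly noiseless cohort."""
    outdir = tmp_path_factory.mktemp("cohort_noiseless")
    truth = simulate_cohort(small_cohort_config(seed=5, noise_sigma=0.0), outdir)
    return outdir, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
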