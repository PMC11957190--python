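import numpy as np
import pandas as pd
import pytest

from mirmod import synthetic
from mirmod.data_io import ExpressionMatrix, PhenotypeTable


@pytest.fixture(scope="session")
def small_cfg() -> synthetic.SimulationConfig:
    """Small cohort: quick enough for per-test simulation, big enough to fit."""
    return synthetic.SimulationConfig(
        n_participants=120, n_mirnas=12, seed=7, n_modifiers=2, modifier_effect=0.3,
        modifier_adversity="trauma"
    )


@pytest.fixture(scope="session")
def small_bundle(small_cfg) -> synthetic.CohortBundle:
    return synthetic.gen_dataset(small_cfg)


@pytest.fixture()
def tiny_pheno() -> PhenotypeTable:
    """Hand-built five-participant phenotype table across waves 2 and 3."""
    rows = []
    for i in range(5):
        pid = f"P{i}"
        for wave in (2, 3):
            rows.append(
                {
                    "sample_id": f"{pid}_w{wave}",
                    "participant_id": pid,
                    "wave": wave,
                    "ptss": 20 + 3 * i,
                    "trauma_lifetime": i,
                    "financial_lifetime": i % 2,
                    "emotional_lifetime": 0,
                    "discrimination": 3.0 + 0.1 * i,
                    "loneliness": 1.5,
                }
            )
    return PhenotypeTable(pd.DataFrame(rows))


@pytest.fixture()
def tiny_counts() -> ExpressionMatrix:
    rng = np.random.default_rng(3)
    counts = rng.integers(0, 500, size=(4, 3))
    return ExpressionMatrix(
        [f"mir-{i}" for i in range(4)], ["P0_w2", "P1_w2", "P2_w2"], counts
    )


def nb_sample(rng: np.random.Generator, mean, theta: float) -> np.ndarray:
    """Independent NB sampler for test data (gamma-Poisson mixture)."""
    mean = np.asarray(mean, dtype=float)
    return rng.poisson(rng.gamma(theta, mean / theta))
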