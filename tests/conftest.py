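import warnings

import numpy as np
import pandas as pd
import pytest

import lipidcad as lc


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-structure cohort shared by read-only tests."""
    cfg = lc.SimulationConfig(n_study=300, n_species=120, seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clinical, lipids, labels, truth = lc.simulate_cohort(cfg)
    return cfg, clinical, lipids, labels, truth


@pytest.fixture(scope="session")
def batchless_cohort():
    """Cohort with no batch effects and no planted class signal."""
    cfg = lc.SimulationConfig(
        n_study=250, n_species=80, batch_sd=0.0, n_informative=0, seed=7
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clinical, lipids, labels, truth = lc.simulate_cohort(cfg)
    return cfg, clinical, lipids, labels, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_clinical_frame(n, seed=0, **overrides):
    """Hand-rolled minimal clinical table for unit tests."""
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "sample_id": [f"P{i:04d}" for i in range(n)],
            "role": "study",
            "age": rng.normal(60, 10, n).clip(30, 85),
            "sex": rng.choice(["F", "M"], n),
            "bmi": rng.normal(27, 5, n).clip(17, 45),
            "hypertension": rng.random(n) < 0.4,
            "diabetes": rng.random(n) < 0.1,
            "hypercholesterolemia": rng.random(n) < 0.5,
            "current_smoking": rng.random(n) < 0.1,
            "statin": False,
            "sbp": rng.normal(130, 15, n).clip(95, 200),
            "tc": rng.normal(5.5, 1.0, n).clip(3, 9),
            "hdl": rng.normal(1.4, 0.3, n).clip(0.6, 2.5),
            "cac": 0.0,
            "batch": "B1",
            "recruit_order": np.arange(1, n + 1),
        }
    )
    for key, val in overrides.items():
        frame[key] = val
    return frame
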