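import numpy as np
import pandas as pd
import pytest

from wormfit.metrics import add_fitness_columns
from wormfit.simulate import MethodError, full_design_config, simulate_assay

NO_ERROR = {m: MethodError() for m in ("by_eye", "cellprofiler", "sorter")}


@pytest.fixture(scope="session")
def full_sim():
    """One full-design simulated assay (5 blocks x 18 combos x 24 reps,
    by-eye missing from one block), with fitness estimators attached."""
    obs, truth = simulate_assay(full_design_config(seed=7))
    return add_fitness_columns(obs), truth


@pytest.fixture(scope="session")
def clean_sim():
    """Same design with counting error switched off (pure biology + binomial)."""
    obs, truth = simulate_assay(full_design_config(seed=11, method_error=NO_ERROR))
    return add_fitness_columns(obs), truth


@pytest.fixture()
def small_obs():
    """A tiny hand-written observation table covering boundary cases."""
    return pd.DataFrame(
        {
            "block_id": ["B1"] * 6,
            "focal_strain": ["N2"] * 6,
            "competitor_strain": ["ST2"] * 6,
            "method": ["by_eye"] * 3 + ["sorter"] * 3,
            "replicate_id": [f"r{i}" for i in range(6)],
            "n_total": [100, 100, 100, 50, 50, 50],
            "n_gfp": [60, 50, 40, 0, 25, 50],
        }
    )


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same deterministic stream
    return np.random.default_rng(20240917)
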