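import numpy as np
import pandas as pd
import pytest

from npqflow import CohortSimConfig, ProteomicsMatrix, simulate_cohort, simulate_survival


@pytest.fixture(scope="session")
def small_cfg() -> CohortSimConfig:
    """A scaled-down cohort (~275 samples, 40 analytes) for fast stage tests."""
    return CohortSimConfig(seed=42, n_analytes=40).scaled(0.1)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    m, meta, truth = simulate_cohort(small_cfg)
    meta = simulate_survival(meta, truth, small_cfg)
    return m, meta, truth


@pytest.fixture()
def tiny_matrix() -> ProteomicsMatrix:
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(3.5, 0.3, (20, 10)),
        index=[f"S{i:02d}" for i in range(20)],
        columns=[f"A{j:02d}" for j in range(10)],
    )
    return ProteomicsMatrix(values, scale="log10")
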