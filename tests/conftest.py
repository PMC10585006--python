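import numpy as np
import pandas as pd
import pytest

from synergysig import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_counts(rng):
    """8-sample (2 per cell) random count matrix with matching design."""
    genes = [f"g{i}" for i in range(40)]
    samples = [f"{c}_r{r}" for c in ("ctrl", "A", "B", "AB") for r in (1, 2)]
    counts = pd.DataFrame(
        rng.poisson(200, size=(40, 8)), index=genes, columns=samples
    )
    design = pd.DataFrame(
        {
            "sample": samples,
            "treat_a": [0, 0, 1, 1, 0, 0, 1, 1],
            "treat_b": [0, 0, 0, 0, 1, 1, 1, 1],
            "time": "20h",
            "replicate": [1, 2] * 4,
        }
    )
    return counts, design


@pytest.fixture(scope="session")
def factorial_run():
    """One full simulated factorial experiment shared across tests."""
    cfg = simulate.FactorialSimConfig(seed=11)
    return simulate.gen_factorial_counts(cfg)
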