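import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

from hifseek import ExpressionStudy, SimConfig  # noqa: E402


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A small but complete synthetic study configuration."""
    return SimConfig(
        n_genes=200,
        genome_length=1_200_000,
        n_chromosomes=1,
        n_peaks=8,
        n_decoy_peaks=1,
        seed=7,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_balanced_study(
    n_genes: int,
    treatments=("A", "B", "C", "D"),
    n_blocks: int = 3,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ExpressionStudy:
    """Random balanced-design study with pure-noise expression."""
    rng = np.random.default_rng(seed)
    cols, rows = [], []
    for b in range(1, n_blocks + 1):
        for t in treatments:
            cols.append(f"b{b}_{t}")
            rows.append({"sample": f"b{b}_{t}", "genotype": t,
                         "treatment": t, "block": b})
    matrix = pd.DataFrame(
        rng.normal(5.0, noise_sd, size=(n_genes, len(cols))),
        index=[f"g{i}" for i in range(n_genes)],
        columns=cols,
    )
    samples = pd.DataFrame(rows).set_index("sample")
    return ExpressionStudy(matrix, samples)


@pytest.fixture()
def balanced_study() -> ExpressionStudy:
    return make_balanced_study(50)
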