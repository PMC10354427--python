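import numpy as np
import pandas as pd
import pytest

from droughtstab.genomics import GenotypeMatrix, RelationshipMatrix
from droughtstab.spectral import TimeSeriesTrait
from droughtstab.stability import EnvironmentTable
from droughtstab.synthetic_data import SyntheticConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study reused across modules (150 genotypes, defaults)."""
    return simulate_study(SyntheticConfig(n_genotypes=150, n_markers=800, seed=11))


@pytest.fixture(scope="session")
def small_kinship():
    """A well-conditioned correlation-like 40x40 relationship matrix."""
    rng = np.random.default_rng(5)
    A = rng.standard_normal((40, 120)) / np.sqrt(120)
    G = A @ A.T + 0.1 * np.eye(40)
    d = np.sqrt(np.diag(G))
    G = G / np.outer(d, d)
    return RelationshipMatrix(values=G, genotype_ids=[f"g{i}" for i in range(40)])


@pytest.fixture
def toy_trait():
    """6 genotypes x 4 timepoints with genotype-specific trends."""
    rng = np.random.default_rng(3)
    das = np.array([35.0, 45.0, 55.0, 65.0])
    ids = [f"g{i}" for i in range(6)]
    u0 = rng.normal(0, 0.1, 6)
    u1 = rng.normal(0, 0.06, 6)
    x = -1 + 2 * (das - das.min()) / (das.max() - das.min())
    y = 0.7 - 0.1 * (x + 1) / 2
    Y = y[None, :] + u0[:, None] + u1[:, None] * x[None, :] + rng.normal(0, 0.03, (6, 4))
    return TimeSeriesTrait(values=pd.DataFrame(Y, index=ids), timepoints=das)


@pytest.fixture
def toy_weights():
    vals = pd.DataFrame(
        {
            "e1": [10.0, 12.0, 14.0, 16.0],
            "e2": [20.0, 26.0, 23.0, 29.0],
            "e3": [5.0, 9.0, 7.0, 11.0],
        },
        index=["g0", "g1", "g2", "g3"],
    )
    return EnvironmentTable(values=vals)
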