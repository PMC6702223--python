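import numpy as np
import pandas as pd
import pytest

from twinconn.synthetic import (TwinCohortSpec, VarianceComponentsSpec,
                                simulate_twin_phenotypes)
from twinconn.twin_models import TwinPairObservation, pairs_from_table


@pytest.fixture(scope="session")
def ae_pairs_large():
    """2000+2000 pairs generated under AE with a2=0.6."""
    spec = TwinCohortSpec(n_mz=2000, n_dz=2000,
                          components=VarianceComponentsSpec(a2=0.6, e2=0.4), seed=2)
    return pairs_from_table(simulate_twin_phenotypes(spec))


@pytest.fixture(scope="session")
def small_pairs():
    """Small deterministic mixed-zygosity pair set for structural tests."""
    rng = np.random.default_rng(7)
    pairs = [TwinPairObservation(f"mz{i}", "MZ", *rng.normal(0.0, 1.0, 2))
             for i in range(20)]
    pairs += [TwinPairObservation(f"dz{i}", "DZ", *rng.normal(0.3, 1.2, 2))
              for i in range(15)]
    return pairs


def make_pairs(r_target, n, zygosity, seed, mean=0.0, var=1.0):
    """Bivariate-normal pairs at a given within-pair correlation."""
    rng = np.random.default_rng(seed)
    cov = np.array([[var, r_target * var], [r_target * var, var]])
    y = mean + rng.multivariate_normal([0.0, 0.0], cov, size=n)
    return [TwinPairObservation(f"{zygosity}{i}", zygosity, y[i, 0], y[i, 1])
            for i in range(n)]


@pytest.fixture
def pair_factory():
    return make_pairs
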