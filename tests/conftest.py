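import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes _oracles importable


def random_weight_matrix(rng, n, density=0.5, binary=False):
    """Random symmetric non-negative weight matrix with zero diagonal."""
    W = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mask = rng.random(len(iu[0])) < density
    vals = np.ones(mask.sum()) if binary else rng.lognormal(0.0, 0.7, mask.sum())
    W[iu[0][mask], iu[1][mask]] = vals
    return W + W.T


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_cohort():
    """10+10 cohort with a strong injected group effect, for pipeline tests."""
    import tractnet as tn

    spec = tn.CohortSpec(n_controls=10, n_patients=10,
                         weak_edge_deletion_prob=0.5, weight_attenuation=0.6,
                         seed=7)
    return tn.simulate_cohort(spec)
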