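import numpy as np
import pytest

from stratacause import SimulationParams, generate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A small generated dataset with ground truth, shared across tests."""
    params = SimulationParams(
        n_features=2000, n_feature_clusters=50, n_pathways=5,
        n_positive_samples=40, n_causal_clusters=2, seed=7,
    )
    return generate_dataset(params)


def make_toy_strata(n_null: int = 4, per_stratum: int = 8, n_neg: int = 14, seed: int = 0):
    """Noiseless two-mechanism toy: two positive strata, each marked by its
    own 3-feature causal cluster, plus outcome-indifferent null features.

    Returns (G, R, truth_strata) with truth_strata in {0, 1, 2} (2 = negative).
    """
    rng = np.random.default_rng(seed)
    n = 2 * per_stratum + n_neg
    strata = np.array([0] * per_stratum + [1] * per_stratum + [2] * n_neg)
    R = np.where(strata < 2, 1, -1).astype(np.int8)
    rows = []
    for k in (0, 1):
        for _ in range(3):
            rows.append((strata == k).astype(np.int8))
    for _ in range(n_null):
        rows.append((rng.random(n) < 0.4).astype(np.int8))
    G = np.array(rows, dtype=np.int8)
    return G, R, strata
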