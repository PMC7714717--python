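import warnings

import numpy as np
import pytest

import phenopipe as pp


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    # convergence warnings from deliberately tiny / degenerate fits are noise
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        yield


@pytest.fixture(scope="session")
def small_design():
    # 24 genotypes x 3 reps in 4 blocks of 6 on a 9x8 grid
    return pp.make_design(24, 3, 4, 9, 8, seed=11)


@pytest.fixture(scope="session")
def small_trial(small_design):
    return pp.simulate_trial(small_design, 10, 0.7, seed=5)


@pytest.fixture(scope="session")
def tiny_design():
    # 12 genotypes x 2 reps in 3 blocks of 4 on a 6x4 grid
    return pp.make_design(12, 2, 3, 6, 4, seed=3)


@pytest.fixture(scope="session")
def tiny_trial(tiny_design):
    return pp.simulate_trial(tiny_design, 8, 0.7, seed=7)


def pearson(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    return float(np.corrcoef(a[keep], b[keep])[0, 1])
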