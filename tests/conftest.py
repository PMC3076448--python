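import numpy as np
import pytest

from curvafm import default_nn_parameters, default_step_table
from curvafm.sequence import GenomicSequence


@pytest.fixture(scope="session")
def step_table():
    return default_step_table()


@pytest.fixture(scope="session")
def nn_params():
    return default_nn_parameters()


@pytest.fixture()
def random_sequence():
    def make(n=300, seed=0, origin=1):
        rng = np.random.default_rng(seed)
        return GenomicSequence(
            "".join(rng.choice(list("ACGT"), size=n)), origin=origin
        )

    return make


def kabsch_rmsd(P, Q):
    """RMSD after optimal rigid superposition (proper rotations only)."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return float(np.sqrt(np.mean(np.sum((Q - P @ R.T) ** 2, axis=1))))


@pytest.fixture(scope="session")
def rmsd():
    return kabsch_rmsd
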