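import numpy as np
import pytest

import msngrad as mg


@pytest.fixture(scope="session")
def partition150():
    return mg.generate_partition(150, 4, seed=1)


@pytest.fixture(scope="session")
def small_cohort(partition150):
    spec = mg.CohortSpec(n_subjects=24, n_regions=150, n_networks=4, seed=3)
    return mg.generate_cohort(spec, partition150)


@pytest.fixture(scope="session")
def small_msns(small_cohort):
    return [mg.build_msn(s.X) for s in small_cohort]


def random_rotation(k, rng):
    """Haar-ish random orthogonal matrix (QR with sign fix)."""
    A = rng.standard_normal((k, k))
    Q, R = np.linalg.qr(A)
    return Q * np.sign(np.diag(R))
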