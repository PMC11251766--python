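import numpy as np
import pytest

from cwmorph import CohortSpec, default_topology, make_template, simulate_cohort


@pytest.fixture(scope="session")
def template():
    return make_template()


@pytest.fixture(scope="session")
def topology(template):
    return default_topology(template)


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, dropout-free cohort: ground truth is exactly recoverable."""
    return CohortSpec(
        n_subjects=3, posture="SIT", noise_sd=0.0, dropout_prob=0.0,
        subject_shape_sd=4.0, duration_s=16.0, seed=11,
    )


@pytest.fixture(scope="session")
def clean_cohort(clean_spec):
    return simulate_cohort(clean_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng) -> np.ndarray:
    """Haar-ish random proper rotation via QR."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
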