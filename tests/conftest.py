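import numpy as np
import pytest

from cohenpois import FrequencyTable, load_fixture


@pytest.fixture(scope="session")
def horsekick_altered() -> FrequencyTable:
    return load_fixture("horsekick_altered")


@pytest.fixture(scope="session")
def horsekick_original() -> FrequencyTable:
    return load_fixture("horsekick_original")


@pytest.fixture(scope="session")
def traffic_altered() -> FrequencyTable:
    return load_fixture("traffic_altered")


@pytest.fixture(scope="session")
def traffic_original() -> FrequencyTable:
    return load_fixture("traffic_original")


def draw_joint_model(rng: np.random.Generator, n_reps: int, sample_size: int,
                     mean=(0.7, 0.7), sd=(0.1, 0.1)):
    """Vectorised draws from the joint (prior x sampling) model.

    The prior is the independent two-point distribution with each
    component at mean +/- sd with probability 1/2, so it has exactly the
    requested mean and diagonal covariance.  Returns the parameter draws
    and the per-replicate sufficient summaries (n0, n1, xbar).
    """
    lam = mean[0] + sd[0] * rng.choice([-1.0, 1.0], size=n_reps)
    phi = mean[1] + sd[1] * rng.choice([-1.0, 1.0], size=n_reps)
    y = rng.poisson(lam[:, None], size=(n_reps, sample_size))
    hide = (y == 1) & (rng.random((n_reps, sample_size)) < phi[:, None])
    x = np.where(hide, 0, y)
    n0 = (x == 0).sum(axis=1)
    n1 = (x == 1).sum(axis=1)
    xbar = x.mean(axis=1)
    return lam, phi, n0, n1, xbar
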