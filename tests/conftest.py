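import numpy as np
import pytest

from mebci.pipeline import TrialSet

CLASSES = ("mRB", "mFB", "mLS", "mRS")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_channels():
    return ("F3", "Fz", "F4", "C3", "Cz", "C4", "CPz", "Pz")


def make_trialset(rng, n_trials=8, n_samples=400, n_channels=4, fs=1000.0,
                  sessions=(1,)):
    data = rng.standard_normal((n_trials, n_samples, n_channels))
    labels = tuple(CLASSES[i % 4] for i in range(n_trials))
    sid = tuple(sessions[i % len(sessions)] for i in range(n_trials))
    return TrialSet(data, labels, fs, sid)


@pytest.fixture()
def toy_trialset(rng):
    return make_trialset(np.random.default_rng(7))


@pytest.fixture(scope="session")
def coarse_shell_mesh():
    """320-triangle-per-surface three-shell mesh for fast BEM tests."""
    from mebci.forward.geometry import three_shell_mesh

    return three_shell_mesh(subdivisions=2)


@pytest.fixture(scope="session")
def coarse_bem_solution(coarse_shell_mesh):
    from mebci.forward.bem import bem_solution
    from mebci.forward.montage import standard_montage

    montage = standard_montage(scalp_radius=0.1)
    return bem_solution(coarse_shell_mesh, montage)
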