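import numpy as np
import pytest

from actinf.generative_model import GenerativeModel, TMazeConfig, build_tmaze


@pytest.fixture(scope="session")
def tmaze():
    return build_tmaze()


@pytest.fixture(scope="session")
def tmaze_deterministic():
    return build_tmaze(TMazeConfig(p_valid=1.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_toy_model(n_states=2, T=2, identity_A=True, alpha=2.0, beta=2.0,
                   utilities=None, D=None, A_override=None):
    """Tiny fully-enumerable model: n_states states/outcomes, two actions
    (stay / cycle), horizon T, all policies."""
    from actinf.generative_model import enumerate_policies

    N = n_states
    if A_override is not None:
        A = np.asarray(A_override, float)
    else:
        A = np.eye(N) if identity_A else np.full((N, N), 1.0 / N)
    stay = np.eye(N)
    cycle = np.roll(np.eye(N), 1, axis=0)
    B = np.stack([stay, cycle])
    if utilities is None:
        utilities = np.linspace(1.0, 0.0, N)
    if D is None:
        D = np.full(N, 1.0 / N)
    V = enumerate_policies(2, T - 1)
    return GenerativeModel(A=A, B=B, C_utilities=np.asarray(utilities, float),
                           D=np.asarray(D, float), V=V, T=T,
                           alpha=alpha, beta=beta)


@pytest.fixture()
def toy2():
    return make_toy_model(2, T=2)


@pytest.fixture()
def toy3():
    # partially observable: a noisy but informative likelihood
    A = [[0.7, 0.2, 0.1], [0.2, 0.7, 0.2], [0.1, 0.1, 0.7]]
    return make_toy_model(3, T=3, A_override=A, utilities=[1.0, 0.0, -1.0])
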