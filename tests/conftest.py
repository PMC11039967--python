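import numpy as np
import pytest

from sit2walk import fixtures_synthetic as fx
from sit2walk import model_core as mc


@pytest.fixture(scope="session")
def scenes():
    return fx.toy_scenes()


@pytest.fixture(scope="session")
def model():
    return fx.default_model()


@pytest.fixture(scope="session")
def arrays(model):
    return mc.compile_model(model)


@pytest.fixture(scope="session")
def seated_state(model):
    return fx.seated_initial_state(model)


def synthetic_trajectory(model, t, **series):
    """Build a Trajectory on `model` from fabricated series (zeros elsewhere).

    Accepted keys: q, qd, qdd (n x 11), a, u, F, lnorm, vnorm (n x 20),
    sph_n (n x ns), sph_f (n x ns x 2), trunk_tau, knee_lim (n x 2).
    """
    ar = mc.compile_model(model)
    n = len(t)
    nm, ns, nd = ar.nm, ar.ns, ar.ndof

    def get(name, shape):
        x = series.get(name)
        return np.zeros(shape) if x is None else np.asarray(x, dtype=float)

    return mc.Trajectory(
        model=model, t=np.asarray(t, dtype=float),
        q=get("q", (n, nd)), qd=get("qd", (n, nd)), qdd=get("qdd", (n, nd)),
        u=get("u", (n, nm)), a=get("a", (n, nm)), F=get("F", (n, nm)),
        lnorm=series.get("lnorm", np.ones((n, nm))),
        vnorm=get("vnorm", (n, nm)),
        sph_f=get("sph_f", (n, ns, 2)), sph_n=get("sph_n", (n, ns)),
        trunk_tau=get("trunk_tau", (n, 2)), knee_lim=get("knee_lim", (n, 2)),
        mode=np.zeros(n, dtype=np.int64), phase=np.zeros((n, 2), dtype=np.int64))
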