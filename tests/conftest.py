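import numpy as np
import pytest

import lassofold as lf
from lassofold.fixtures import MiniLassoParams, make_mini_lasso


def random_open_chain(n, seed, min_sep=1.123):
    """Self-avoiding random reference chain built from internal coordinates.

    The default separation bound exceeds the WCA cutoff 2^(1/6), so no
    non-bonded pair of the reference feels steric repulsion: the native
    angles are then the true energy minimum (no steric frustration).
    """
    rng = np.random.default_rng(seed)
    for _ in range(200):
        c = lf.build_chain_from_internal(
            np.full(n - 1, 0.96),
            rng.uniform(1.7, 2.7, n - 2),
            rng.uniform(-np.pi, np.pi, n - 3),
        )
        d = np.linalg.norm(c.positions[:, None] - c.positions[None, :], axis=-1)
        iu = np.triu_indices(n, k=2)
        if d[iu].min() > min_sep:
            return c
    raise RuntimeError("no self-avoiding chain found")


@pytest.fixture(scope="session")
def mini_lasso():
    """Default synthetic L2 mini-lasso: (conf, ref, spec)."""
    return make_mini_lasso(MiniLassoParams(seed=0))


@pytest.fixture(scope="session")
def mini_lasso_l1():
    return make_mini_lasso(MiniLassoParams(lasso_class="L1", seed=0))


@pytest.fixture(scope="session")
def small_reference():
    """12-bead self-avoiding reference chain with a bridge between the ends."""
    native = random_open_chain(12, seed=4)
    ref = lf.extract_reference_geometry(native, bridge_pairs=[(1, 12)])
    return native, ref


@pytest.fixture(scope="session")
def efm_model(small_reference):
    native, ref = small_reference
    params = lf.ModelParameters(temperature=0.1)
    bridges = lf.BridgeParameters.from_reference(ref, kBT=0.1)
    return lf.EFMModel(ref, lf.ForceField.homogeneous(12), params, bridges)


def finite_difference_forces(model, pos, h=1e-6):
    fd = np.zeros_like(pos)
    for i in range(pos.shape[0]):
        for d in range(3):
            pp = pos.copy()
            pp[i, d] += h
            pm = pos.copy()
            pm[i, d] -= h
            fd[i, d] = -(model.energy(pp) - model.energy(pm)) / (2 * h)
    return fd
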