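import numpy as np
import pytest

import maeeqe as m


@pytest.fixture(scope="session")
def small_scene():
    """One 40 x 80 synthetic scene shared across read-only tests."""
    return m.make_scene(m.SceneConfig(shape=(40, 80), seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def full_lattice(values_2d):
    """UnitLattice covering a full 2-D array, one unit per cell."""
    arr = np.asarray(values_2d, dtype=float)
    nr, nc = arr.shape
    pos = np.array([[r, c] for r in range(nr) for c in range(nc)])
    return m.UnitLattice(values=arr.ravel(), positions=pos, unit_size=1.0,
                         coverage=np.ones(arr.size), lattice_shape=(nr, nc))


def naive_global_moran(y, W):
    """Literal double-loop global Moran's I (standard normalization)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    d = y - y.mean()
    num = s0 = 0.0
    for i in range(n):
        for jj, j in enumerate(W.neighbors[i]):
            w = W.weights[i][jj]
            num += w * d[i] * d[j]
            s0 += w
    return (n / s0) * num / (d @ d)


def naive_local_moran(y, W):
    """Literal per-unit local Moran (printed n scaling)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    d = y - y.mean()
    m2 = d @ d
    out = np.empty(n)
    for i in range(n):
        lag = sum(w * d[j] for j, w in zip(W.neighbors[i], W.weights[i]))
        out[i] = n * d[i] * lag / m2
    return out
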