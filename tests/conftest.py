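import numpy as np
import pytest

from biocarbon import ExpL1Kernel, cell_areas, make_world
from biocarbon.persistence import SimilarityKernel


class DeltaKernel(SimilarityKernel):
    """s(x, y) = 1 iff x == y exactly, else 0 — handy for exact-weight tests."""

    def pairwise(self, x, y):
        x = np.atleast_2d(np.asarray(x, float))
        y = np.atleast_2d(np.asarray(y, float))
        return np.all(x[:, None, :] == y[None, :, :], axis=2).astype(float)


@pytest.fixture(scope="session")
def kernel():
    return ExpL1Kernel(sigma=1.0)


@pytest.fixture
def delta_kernel():
    return DeltaKernel()


@pytest.fixture(scope="session")
def small_world():
    """A compact default-conditions world shared by read-only tests."""
    return make_world(seed=42, n_lat=10, n_lon=12, n_ecoregions=6)


@pytest.fixture(scope="session")
def small_world_areas(small_world):
    return cell_areas(small_world.grid)


def brute_force_effective_present(env, areas, kernel):
    """Independent O(n²) oracle: explicit double loop over cell pairs."""
    x = np.asarray(env, float).reshape(-1, env.shape[-1])
    a = np.asarray(areas, float).ravel()
    n = len(a)
    out = np.zeros(n)
    for j in range(n):
        for i in range(n):
            out[j] += kernel(x[j], x[i]) * a[i]
    return out


def brute_force_effective_scenario(env_p, env_f, cond_f, areas, kernel):
    xp = np.asarray(env_p, float).reshape(-1, env_p.shape[-1])
    xf = np.asarray(env_f, float).reshape(-1, env_f.shape[-1])
    h = np.asarray(cond_f, float).ravel()
    a = np.asarray(areas, float).ravel()
    n = len(a)
    out = np.zeros(n)
    for j in range(n):
        for i in range(n):
            out[j] += kernel(xp[j], xf[i]) * h[i] * a[i]
    return out
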