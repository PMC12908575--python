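import numpy as np
import pytest

from bcti import ExpressionMatrix


def make_expr(values, gene_prefix="g", sample_prefix="s"):
    """ExpressionMatrix from a raw array with auto-generated ids."""
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return ExpressionMatrix(
        [f"{gene_prefix}{i + 1}" for i in range(m)],
        [f"{sample_prefix}{j + 1}" for j in range(n)],
        values,
    )


def correlated_pair(rho, n=30, seed=0):
    """Two vectors with *exact* sample Pearson correlation ``rho``.

    Built from two orthonormal centered basis vectors, so the empirical
    correlation equals rho to machine precision.
    """
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(n)
    u -= u.mean()
    u /= np.linalg.norm(u)
    w = rng.standard_normal(n)
    w -= w.mean()
    w -= (w @ u) * u
    w /= np.linalg.norm(w)
    return u, rho * u + np.sqrt(1 - rho**2) * w


def linear_system_4(seed, n=40, noise=0.5):
    """g1 -> g2 -> g3, g1 & g3 -> g4 with Gaussian noise."""
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n)
    x2 = 1.2 * x1 + noise * rng.standard_normal(n)
    x3 = -0.9 * x2 + noise * rng.standard_normal(n)
    x4 = 0.8 * x1 + 0.7 * x3 + noise * rng.standard_normal(n)
    return make_expr(np.vstack([x1, x2, x3, x4]))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
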