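"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from scipy.integrate import quad_vec
from scipy.linalg import expm

from induce.langevin_core import NetworkModel


def quadrature_sigma0(A: np.ndarray, Q: np.ndarray, rtol: float = 1e-12) -> np.ndarray:
    """Brute-force stationary covariance ∫₀^∞ e^{At} QQᵀ e^{Aᵀt} dt.

    Independent oracle for the Lyapunov solver: direct quadrature of the
    defining integral, truncated where the integrand has decayed to
    round-off.
    """
    A = np.asarray(A, dtype=float)
    D = np.asarray(Q, dtype=float) @ np.asarray(Q, dtype=float).T
    decay = -np.max(np.linalg.eigvals(A).real)
    t_max = 60.0 / decay

    def integrand(t):
        E = expm(A * t)
        return E @ D @ E.T

    val, _ = quad_vec(integrand, 0.0, t_max, epsabs=1e-13, epsrel=rtol)
    return val


def random_stable_system(rng: np.random.Generator, n: int, m: int | None = None,
                         skew_scale: float = 0.5) -> NetworkModel:
    """Random Hurwitz system: negative-definite symmetric part plus skew part."""
    m = n if m is None else m
    B = rng.standard_normal((n, n))
    S = rng.standard_normal((n, n))
    A = -(B @ B.T + 0.2 * np.eye(n)) + skew_scale * (S - S.T)
    Q = rng.standard_normal((n, m))
    return NetworkModel(A=A, Q=Q)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
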