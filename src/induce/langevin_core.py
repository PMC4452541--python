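"""Stationary linear Langevin (multivariate Ornstein--Uhlenbeck) algebra.

A network of N species fluctuating around a stable fixed point follows

    dx/dt = A x + Q ξ,

with ``A`` the connectivity matrix (a_ji = rate of change of species j per
unit deviation of species i, units 1/time), ``Q`` the noise-amplitude
matrix and ``ξ`` a vector of independent unit white noises.  At
stationarity the covariance matrix Σ₀ of ``x`` is tied to (A, Q) by the
continuous Lyapunov equation

    A Σ₀ + Σ₀ Aᵀ + QQᵀ = 0,

and the lagged covariance is Σ(τ) = Σ₀ exp(Aᵀ τ).  This module provides
the forward solve (A, Q) → Σ₀, the lagged covariance, and the analytic
inverse maps: the general solution A = (−½QQᵀ + U)Σ₀⁻¹ with U
antisymmetric, and the thermal-bath special case A = −Σ₀⁻¹ k_BT.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.linalg import expm, solve_continuous_lyapunov

from induce.errors import InputError, NumericalError, StabilityError

#: eigenvalue real-part tolerance separating stable from marginal systems
TOL_STAB = 1e-10

#: acceptable relative residual of the Lyapunov identity for solver outputs
LYAPUNOV_RTOL = 1e-8


def is_stable(A: np.ndarray, tol: float = TOL_STAB) -> bool:
    """True iff every eigenvalue of ``A`` has real part < ``-tol`` (Hurwitz)."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InputError(f"A must be square, got shape {A.shape}")
    return bool(np.max(np.linalg.eigvals(A).real) < -tol)


@dataclass
class NetworkModel:
    """Linear Langevin system (A, Q) with optional species labels.

    Parameters
    ----------
    A : (N, N) array
        Connectivity matrix; must be Hurwitz for a stationary state.
    Q : (N, M) array
        Noise amplitudes; ``QQᵀ`` is the diffusion matrix.
    labels : list of str, optional
        Species names, defaults to ``x1..xN``.
    """

    A: np.ndarray
    Q: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        if self.A.shape[0] != self.A.shape[1]:
            raise InputError(f"A must be square, got shape {self.A.shape}")
        if self.Q.shape[0] != self.A.shape[0]:
            raise InputError(
                f"Q has {self.Q.shape[0]} rows but A is {self.A.shape[0]}x{self.A.shape[0]}"
            )
        if not self.labels:
            self.labels = [f"x{i + 1}" for i in range(self.N)]
        if len(self.labels) != self.N:
            raise InputError("labels length must equal the number of species")

    @property
    def N(self) -> int:
        return self.A.shape[0]

    @property
    def M(self) -> int:
        return self.Q.shape[1]

    @property
    def diffusion(self) -> np.ndarray:
        """QQᵀ, the (symmetric PSD) diffusion matrix."""
        return self.Q @ self.Q.T

    def is_stable(self, tol: float = TOL_STAB) -> bool:
        return is_stable(self.A, tol)

    # -- plain-text round trip -------------------------------------------

    def to_dict(self) -> dict:
        return {
            "A": self.A.tolist(),
            "Q": self.Q.tolist(),
            "labels": list(self.labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModel":
        try:
            return cls(A=np.array(d["A"], dtype=float),
                       Q=np.array(d["Q"], dtype=float),
                       labels=list(d.get("labels", [])))
        except KeyError as e:
            raise InputError(f"missing field {e} in network config") from e

    def save(self, path) -> None:
        """Write a YAML (or JSON, by extension) description of the model."""
        text = (json.dumps(self.to_dict(), indent=2)
                if str(path).endswith(".json")
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        with open(path, "w") as fh:
            fh.write(text)

    @classmethod
    def load(cls, path) -> "NetworkModel":
        with open(path) as fh:
            d = yaml.safe_load(fh)  # YAML superset also parses JSON
        if not isinstance(d, dict):
            raise InputError(f"network config {path} does not contain a mapping")
        return cls.from_dict(d)


@dataclass
class StationaryCovariance:
    """Symmetric PSD stationary covariance Σ₀ with element accessors."""

    Sigma0: np.ndarray

    def __post_init__(self) -> None:
        S = np.atleast_2d(np.asarray(self.Sigma0, dtype=float))
        if S.shape[0] != S.shape[1]:
            raise InputError(f"Sigma0 must be square, got shape {S.shape}")
        # symmetrize away roundoff so invariants are exactly assertable
        self.Sigma0 = (S + S.T) / 2.0
        w = np.linalg.eigvalsh(self.Sigma0)
        if w[0] < -1e-10 * max(w[-1], 1e-300):
            raise NumericalError(
                f"Sigma0 not positive semidefinite (min eigenvalue {w[0]:.3e})"
            )

    @property
    def N(self) -> int:
        return self.Sigma0.shape[0]

    def var(self, i: int) -> float:
        """Variance σᵢ² of species ``i`` (0-based)."""
        return float(self.Sigma0[i, i])

    def cov(self, i: int, j: int) -> float:
        """Covariance σᵢⱼ between species ``i`` and ``j``."""
        return float(self.Sigma0[i, j])


@dataclass
class LaggedCovariance:
    """Lagged covariance Σ(τ) = Σ₀ exp(Aᵀτ) at a nonnegative lag τ."""

    tau: float
    Sigma_tau: np.ndarray

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise InputError(f"lag tau must be nonnegative, got {self.tau}")
        self.Sigma_tau = np.atleast_2d(np.asarray(self.Sigma_tau, dtype=float))


def solve_lyapunov(model: NetworkModel) -> StationaryCovariance:
    """Stationary covariance of the linear Langevin system.

    Solves ``A Σ₀ + Σ₀ Aᵀ + QQᵀ = 0`` by a direct dense (Bartels--Stewart)
    solve, then symmetrizes.  Raises :class:`StabilityError` if ``A`` is not
    Hurwitz, and :class:`NumericalError` if the residual exceeds tolerance.
    """
    A = model.A
    lam = np.linalg.eigvals(A)
    worst = lam[np.argmax(lam.real)]
    if worst.real >= -TOL_STAB:
        raise StabilityError(
            f"A is not stable: eigenvalue {worst:.6g} has real part >= {-TOL_STAB:g}"
        )
    D = model.diffusion
    Sigma0 = solve_continuous_lyapunov(A, -D)
    resid = np.linalg.norm(A @ Sigma0 + Sigma0 @ A.T + D, "fro")
    scale = np.linalg.norm(D, "fro")
    if scale > 0 and resid / scale > LYAPUNOV_RTOL:
        raise NumericalError(
            f"Lyapunov residual {resid / scale:.3e} exceeds {LYAPUNOV_RTOL:g}"
        )
    return StationaryCovariance(Sigma0)


def lagged_covariance(
    model: NetworkModel, Sigma0: StationaryCovariance, tau: float
) -> LaggedCovariance:
    """Σ(τ) = Σ₀ exp(Aᵀτ) for a nonnegative lag ``tau``.

    ``Sigma0`` is assumed to solve the Lyapunov equation for ``model``;
    at ``tau == 0`` the result equals ``Sigma0`` exactly.
    """
    if tau < 0:
        raise InputError(f"lag tau must be nonnegative, got {tau}")
    S = Sigma0.Sigma0 @ expm(model.A.T * tau)
    return LaggedCovariance(tau=float(tau), Sigma_tau=S)


def network_from_U(
    Q: np.ndarray, U: np.ndarray, Sigma0: StationaryCovariance,
    atol: float = 1e-10,
) -> NetworkModel:
    """General Lyapunov inverse: A = (−½QQᵀ + U)·Σ₀⁻¹ with U antisymmetric.

    Any antisymmetric ``U`` yields a connectivity consistent with the given
    noise and covariance — the degeneracy that makes correlation alone
    insufficient for causation.  The returned model satisfies the Lyapunov
    equation for (Q, Σ₀) by construction.
    """
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if np.linalg.norm(U + U.T) > atol * max(1.0, np.linalg.norm(U)):
        raise InputError("U is not antisymmetric")
    S = Sigma0.Sigma0
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e12:
        raise NumericalError(f"Sigma0 is singular or near-singular (cond={cond:.3e})")
    A = (-0.5 * Q @ Q.T + U) @ np.linalg.inv(S)
    return NetworkModel(A=A, Q=Q)


def thermal_network(Sigma0: StationaryCovariance, kBT: float) -> NetworkModel:
    """Thermal-bath special case: symmetric A = −Σ₀⁻¹·k_BT, QQᵀ = 2k_BT·I.

    For a conservative system in contact with a bath at temperature T the
    connectivity is proportional to the *inverse* covariance — connection
    strengths are precision-matrix, not covariance, elements.  The
    isotropic noise carries the fluctuation–dissipation factor
    QQᵀ = 2k_BT·I, which is what makes A consistent with the general
    solution (−½QQᵀ + U)Σ₀⁻¹ at U = 0.
    """
    if kBT <= 0:
        raise InputError(f"kBT must be positive, got {kBT}")
    S = Sigma0.Sigma0
    w = np.linalg.eigvalsh(S)
    if w[0] <= 1e-12 * max(w[-1], 1e-300):
        raise NumericalError("Sigma0 must be strictly positive definite")
    Sinv = np.linalg.inv(S)
    A = -kBT * (Sinv + Sinv.T) / 2.0
    Q = np.sqrt(2.0 * kBT) * np.eye(S.shape[0])
    return NetworkModel(A=A, Q=Q)
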