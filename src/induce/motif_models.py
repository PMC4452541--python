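"""Covariance predictions for small network motifs along a dose sweep.

The motifs — an isolated directed edge (``two_node``), convergent
regulation of one target by two sources (``convergent``), and a linear
cascade (``cascade``) — are parameterized by Hill transfer functions
between species and per-species decay rates and intrinsic log-noise
magnitudes.  Linearizing the log-concentration dynamics around the
fixed point at each dose gives an Ornstein--Uhlenbeck system

    dδy_j/dt = Σ_{i≠j} a_ji δy_i − λ_j δy_j + q_j ε_j,

with the connection strength a_ji = λ_j ∂ln f_ji/∂ln x_i evaluated at
the dose-dependent mean ⟨x_i⟩.  Sweeping the dose sweeps a_ji along the
transfer function and traces a parametric path of covariance-matrix
elements: for an isolated edge, σ₁² is constant and σ₂² is a quadratic
in σ₁₂ (the signature the inference pipeline fits); for motifs with a
second, differentially dose-sensitive noise source the path can fail to
be single-valued — an "open loop", the hallmark of an unmeasured
upstream species.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from induce.errors import InputError, StabilityError
from induce.langevin_core import NetworkModel, StationaryCovariance, solve_lyapunov

MOTIF_EDGES = {
    # edges as (source, target) in 0-based node indices
    "two_node": [(0, 1)],
    "convergent": [(0, 1), (2, 1)],
    "cascade": [(2, 0), (0, 1)],
}

#: measured species are always nodes 1 and 2 (indices 0 and 1)
MEASURED = (0, 1)


@dataclass(frozen=True)
class HillTransfer:
    """Saturating Hill dose/transfer response.

    Activation: f(x) = ν xⁿ / (Kⁿ + xⁿ); repression uses the complementary
    decreasing form f(x) = ν Kⁿ / (Kⁿ + xⁿ).  ``nu`` is the saturated
    response amplitude (concentration units), ``K`` the half-response
    concentration and ``n`` the (positive) Hill coefficient; repression is
    a flag rather than a negative exponent.
    """

    nu: float
    K: float
    n: float
    repression: bool = False

    def __post_init__(self) -> None:
        if self.nu <= 0 or self.K <= 0 or self.n <= 0:
            raise InputError(
                f"HillTransfer requires nu, K, n > 0; got nu={self.nu}, K={self.K}, n={self.n}"
            )

    def __call__(self, x):
        return hill_response(x, self)

    def to_dict(self) -> dict:
        return {"nu": self.nu, "K": self.K, "n": self.n, "repression": self.repression}

    @classmethod
    def from_dict(cls, d: dict) -> "HillTransfer":
        return cls(nu=float(d["nu"]), K=float(d["K"]), n=float(d["n"]),
                   repression=bool(d.get("repression", False)))


@dataclass(frozen=True)
class ConstantTransfer:
    """Flat transfer: constant production, zero connection strength.

    Models a regulator pinned outside its dynamic range (or a severed
    edge, k = 0): the target is produced at a fixed rate regardless of
    the source, so no fluctuations propagate.
    """

    level: float

    def __post_init__(self) -> None:
        if self.level <= 0:
            raise InputError(f"ConstantTransfer level must be positive, got {self.level}")

    def __call__(self, x):
        return hill_response(x, self)

    def to_dict(self) -> dict:
        return {"constant": self.level}

    @classmethod
    def from_dict(cls, d: dict) -> "ConstantTransfer":
        return cls(level=float(d["constant"]))


def hill_response(x, h):
    """Evaluate a transfer response at concentration ``x`` ≥ 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise InputError("concentration must be nonnegative")
    if isinstance(h, ConstantTransfer):
        out = np.broadcast_to(np.asarray(h.level, dtype=float), x.shape)
        return float(h.level) if x.ndim == 0 else out.copy()
    xn = x ** h.n
    Kn = h.K ** h.n
    out = h.nu * (Kn if h.repression else xn) / (Kn + xn)
    return float(out) if out.ndim == 0 else out


def log_gain(x, h, lam: float):
    """Connection strength a = λ·∂ln f/∂ln x at the operating point ``x``.

    For activation a = λ n Kⁿ/(Kⁿ+xⁿ) ∈ (0, λn]; for repression the
    decreasing Hill form gives a = −λ n xⁿ/(Kⁿ+xⁿ) ∈ [−λn, 0).  The sign
    of the gain encodes activation (+) versus repression (−).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise InputError("log-gain requires strictly positive concentration")
    if isinstance(h, ConstantTransfer):
        out = np.zeros(x.shape)
        return 0.0 if x.ndim == 0 else out
    xn = x ** h.n
    Kn = h.K ** h.n
    if h.repression:
        out = -lam * h.n * xn / (Kn + xn)
    else:
        out = lam * h.n * Kn / (Kn + xn)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TwoNodeNoiseParams:
    """Reduced parameters of the isolated-edge covariance.

    ``alpha`` = q₁²/(2λ) is the source log-variance floor, ``beta`` =
    q₂²/(2λ) the target's connectivity-independent log-variance, ``lam``
    the shared decay rate and ``k`` the connection strength.
    """

    alpha: float
    beta: float
    lam: float
    k: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.lam <= 0:
            raise InputError("require alpha >= 0, beta >= 0, lam > 0")


def two_node_covariance(p: TwoNodeNoiseParams) -> StationaryCovariance:
    """Closed-form stationary covariance of the isolated directed edge.

    σ₁² = α, σ₁₂ = αk/(2λ), σ₂² = β + αk²/(2λ²) — the analytic Lyapunov
    solution for A = [[−λ, 0], [k, −λ]] with diagonal noise.
    """
    a, b, lam, k = p.alpha, p.beta, p.lam, p.k
    s12 = a * k / (2.0 * lam)
    s22 = b + a * k * k / (2.0 * lam * lam)
    return StationaryCovariance(np.array([[a, s12], [s12, s22]]))


def var2_of_cov(sigma12, alpha: float, beta: float):
    """Target variance as a quadratic in the covariance: σ₂² = β + 2σ₁₂²/α.

    This is the single-valued law an isolated directed edge must satisfy
    along any dose sweep; it is the model the inference pipeline fits.
    """
    if alpha <= 0:
        raise InputError(f"alpha must be positive, got {alpha}")
    sigma12 = np.asarray(sigma12, dtype=float)
    out = beta + 2.0 * sigma12 ** 2 / alpha
    return float(out) if out.ndim == 0 else out


@dataclass
class MotifSpec:
    """Parameterized network motif.

    ``kind`` fixes the edge topology (see ``MOTIF_EDGES``); ``lambdas``
    and ``qs`` are per-node decay rates (1/time) and intrinsic log-noise
    magnitudes; ``edges`` maps each topological edge to its Hill transfer.
    """

    kind: str
    lambdas: Sequence[float]
    qs: Sequence[float]
    edges: dict[tuple[int, int], HillTransfer]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in MOTIF_EDGES:
            raise InputError(
                f"unknown motif kind {self.kind!r}; expected one of {sorted(MOTIF_EDGES)}"
            )
        expected = set(MOTIF_EDGES[self.kind])
        if set(self.edges) != expected:
            raise InputError(
                f"{self.kind} motif requires edges {sorted(expected)}, got {sorted(self.edges)}"
            )
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.qs = np.asarray(self.qs, dtype=float)
        if len(self.lambdas) != self.n_nodes or len(self.qs) != self.n_nodes:
            raise InputError(
                f"{self.kind} motif has {self.n_nodes} nodes; lambdas/qs lengths must match"
            )
        if np.any(self.lambdas <= 0):
            raise InputError("all decay rates must be positive")
        if np.any(self.qs < 0):
            raise InputError("noise magnitudes must be nonnegative")
        if not self.labels:
            self.labels = [f"y{i + 1}" for i in range(self.n_nodes)]

    @property
    def n_nodes(self) -> int:
        return 3 if self.kind in ("convergent", "cascade") else 2

    @property
    def root_nodes(self) -> tuple[int, ...]:
        targets = {t for (_, t) in self.edges}
        return tuple(i for i in range(self.n_nodes) if i not in targets)

    # -- plain-text round trip -------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "lambdas": np.asarray(self.lambdas).tolist(),
            "qs": np.asarray(self.qs).tolist(),
            "edges": [
                {"source": s, "target": t, **h.to_dict()}
                for (s, t), h in sorted(self.edges.items())
            ],
            "labels": list(self.labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MotifSpec":
        try:
            edges = {
                (int(e["source"]), int(e["target"])):
                    (ConstantTransfer.from_dict(e) if "constant" in e
                     else HillTransfer.from_dict(e))
                for e in d["edges"]
            }
            return cls(kind=d["kind"], lambdas=d["lambdas"], qs=d["qs"],
                       edges=edges, labels=list(d.get("labels", [])))
        except KeyError as e:
            raise InputError(f"missing field {e} in motif config") from e

    def save(self, path) -> None:
        text = (json.dumps(self.to_dict(), indent=2)
                if str(path).endswith(".json")
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        with open(path, "w") as fh:
            fh.write(text)

    @classmethod
    def load(cls, path) -> "MotifSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise InputError(f"motif config {path} does not contain a mapping")
        return cls.from_dict(d)


@dataclass
class TrajectoryPoint:
    """Linearization and stationary covariance at one dose."""

    dose: float
    means: np.ndarray          # linear-scale fixed-point means, all nodes
    source_mean: float         # log-scale mean of the measured source (node 1)
    gains: dict[tuple[int, int], float]
    sigma: StationaryCovariance       # restricted to measured nodes (2x2)
    sigma_full: StationaryCovariance  # all nodes


@dataclass
class VarCovPath:
    """Ordered variance-vs-covariance trajectory over a monotone dose grid."""

    points: list[TrajectoryPoint]

    def __len__(self) -> int:
        return len(self.points)

    def series(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Arrays (σ₁₂, σ₁², σ₂²) over the dose grid."""
        s12 = np.array([p.sigma.cov(0, 1) for p in self.points])
        s11 = np.array([p.sigma.var(0) for p in self.points])
        s22 = np.array([p.sigma.var(1) for p in self.points])
        return s12, s11, s22

    @property
    def doses(self) -> np.ndarray:
        return np.array([p.dose for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: dose, covariance elements, per-edge gains."""
        s12, s11, s22 = self.series()
        df = pd.DataFrame({
            "dose": self.doses,
            "sigma12": s12,
            "sigma1_sq": s11,
            "sigma2_sq": s22,
        })
        for (s, t) in sorted(self.points[0].gains):
            df[f"a_{t + 1}{s + 1}"] = [p.gains[(s, t)] for p in self.points]
        return df


def _steady_state_means(
    m: MotifSpec, root_means: dict[int, float],
    damping: float = 0.5, tol: float = 1e-12, max_iter: int = 100_000,
) -> np.ndarray:
    """Fixed-point means from rate balance f = λ·x, damped iteration.

    Root nodes are pinned to their dose-driven means; downstream nodes
    relax to production/decay balance.  The supported motifs are
    feedback-free, so the iteration converges geometrically.
    """
    x = np.ones(m.n_nodes)
    for i, v in root_means.items():
        if v <= 0:
            raise InputError(f"root node {i} mean must be positive, got {v}")
        x[i] = v
    targets = {t for (_, t) in m.edges}
    for _ in range(max_iter):
        x_new = x.copy()
        for j in targets:
            prod = sum(hill_response(x[s], h) for (s, t), h in m.edges.items() if t == j)
            x_new[j] = (1 - damping) * x[j] + damping * prod / m.lambdas[j]
        if np.max(np.abs(x_new - x)) <= tol * max(1.0, np.max(np.abs(x))):
            return x_new
        x = x_new
    return x


def linearize_at(m: MotifSpec, root_means: dict[int, float]) -> tuple[NetworkModel, np.ndarray]:
    """Build the log-deviation OU system (A, Q) at one operating point."""
    x = _steady_state_means(m, root_means)
    A = np.diag(-m.lambdas.astype(float))
    for (s, t), h in m.edges.items():
        A[t, s] = log_gain(x[s], h, m.lambdas[t])
    Q = np.diag(m.qs.astype(float))
    return NetworkModel(A=A, Q=Q, labels=list(m.labels)), x


def motif_trajectory(
    m: MotifSpec,
    doses: Iterable[float],
    dose_map: Callable[[float], dict[int, float]],
) -> VarCovPath:
    """Analytic variance-vs-covariance path of a motif along a dose grid.

    ``dose_map`` maps each dose to the mean linear-scale concentration of
    every root (externally driven) node; downstream means follow from rate
    balance.  At each dose the motif is linearized and the Lyapunov
    equation solved; the returned path restricts the covariance to the two
    measured nodes.
    """
    points: list[TrajectoryPoint] = []
    for dose in doses:
        root_means = dose_map(dose)
        if set(root_means) != set(m.root_nodes):
            raise InputError(
                f"dose_map must supply means for root nodes {m.root_nodes}, got {sorted(root_means)}"
            )
        model, x = linearize_at(m, root_means)
        try:
            full = solve_lyapunov(model)
        except StabilityError as e:
            raise StabilityError(f"unstable linearization at dose {dose}: {e}") from e
        idx = np.asarray(MEASURED)
        sub = StationaryCovariance(full.Sigma0[np.ix_(idx, idx)])
        gains = {
            (s, t): float(model.A[t, s]) for (s, t) in m.edges
        }
        points.append(TrajectoryPoint(
            dose=float(dose), means=x, source_mean=float(np.log(x[0])),
            gains=gains, sigma=sub, sigma_full=full,
        ))
    return VarCovPath(points)


def hill_drive(hills: dict[int, HillTransfer]) -> Callable[[float], dict[int, float]]:
    """Dose map driving each root node's mean through its own Hill response."""

    def _map(dose: float) -> dict[int, float]:
        return {i: float(hill_response(dose, h)) for i, h in hills.items()}

    return _map


def detect_open_loop(
    path: VarCovPath,
    which: int = 1,
    eps_cov: float = 0.02,
    eps_var: float = 0.05,
) -> tuple[bool, float]:
    """Test whether a variance-vs-covariance path fails to be single-valued.

    An isolated directed edge traces a single-valued quadratic in the
    (σ₁₂, variance) plane; a path that revisits the same covariance with a
    materially different variance ("open loop") implicates an unmeasured
    noise source with a different dose sensitivity.

    Operationally: fit a quadratic variance = c₀ + c₁σ₁₂ + c₂σ₁₂², take its
    residual scatter as the baseline, and look for point pairs whose
    covariances agree within ``eps_cov`` × (covariance range) while their
    variances differ by more than ``eps_var`` × (variance range) plus the
    scatter.  Returns (flag, loop score), the score being the largest such
    variance gap normalized by the variance range.
    """
    if len(path) < 4:
        raise InputError(f"open-loop detection needs >= 4 points, got {len(path)}")
    s12, s11, s22 = path.series()
    v = s22 if which == 1 else s11
    cov_range = np.ptp(s12)
    var_range = np.ptp(v)
    if var_range == 0:
        return False, 0.0
    if cov_range == 0:
        # all covariances equal: any variance spread means multivaluedness
        score = 1.0
        return True, score
    X = np.column_stack([np.ones_like(s12), s12, s12 ** 2])
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    scatter = float(np.std(v - X @ coef))
    dc = np.abs(s12[:, None] - s12[None, :])
    dv = np.abs(v[:, None] - v[None, :])
    close = dc <= eps_cov * cov_range
    np.fill_diagonal(close, False)
    gaps = np.where(close, dv, 0.0)
    max_gap = float(gaps.max())
    flag = max_gap > eps_var * var_range + scatter
    score = max_gap / var_range
    return bool(flag), score
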