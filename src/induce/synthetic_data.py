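"""Synthetic single-cell dose-response ensembles with directed noise propagation.

Generates the kind of data the inference pipeline consumes: per-dose
ensembles of single-cell linear-scale intensities whose log-scale
marginals are normal (intensities lognormal), whose per-dose means
follow Hill transfer functions of dose, and whose cross-species
covariance arises from directed propagation of intrinsic fluctuations
through a motif.  Two sampling routes are provided and cross-validated:

* :func:`simulate_ensemble` — exact draws from the stationary
  multivariate normal of the linearized log-deviation dynamics at each
  dose (the ergodic-population route);
* :func:`simulate_sde` — Euler--Maruyama integration of the
  log-deviation Langevin equation for an ensemble of independent cells
  (the temporal route), used to validate the stationary solution
  end-to-end.

Under the ergodic assumption a population snapshot of clonal cells and
the long-time statistics of one cell agree, which is what licenses
estimating the stationary covariance from destructive assays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from induce.errors import InputError, ParseError
from induce.langevin_core import solve_lyapunov
from induce.motif_models import (
    MEASURED,
    HillTransfer,
    MotifSpec,
    VarCovPath,
    hill_drive,
    linearize_at,
    motif_trajectory,
)

@dataclass
class DoseDesign:
    """Experimental design of a synthetic dose-response run.

    ``upstream_drive`` maps dose to the mean linear-scale concentration of
    each externally driven (root) node: a single :class:`HillTransfer`
    (applied to the motif's unique root), a mapping ``{node: HillTransfer}``,
    or an arbitrary callable ``dose -> {node: mean}``.
    """

    doses: Sequence[float]
    upstream_drive: object
    n_cells: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        if len(self.doses) < 1 or np.any(np.diff(self.doses) <= 0):
            raise InputError("doses must be a strictly increasing sequence")
        if self.n_cells < 2:
            raise InputError(f"n_cells must be >= 2, got {self.n_cells}")

    def dose_map(self, m: MotifSpec) -> Callable[[float], dict[int, float]]:
        drive = self.upstream_drive
        if isinstance(drive, HillTransfer):
            roots = m.root_nodes
            if len(roots) != 1:
                raise InputError(
                    f"{m.kind} motif has roots {roots}; supply a per-root drive mapping"
                )
            return hill_drive({roots[0]: drive})
        if isinstance(drive, Mapping):
            return hill_drive(dict(drive))
        if callable(drive):
            return drive
        raise InputError("upstream_drive must be a HillTransfer, mapping, or callable")


@dataclass
class DoseDataset:
    """Per-dose single-cell intensities in linear scale plus provenance.

    ``data`` is a long-format table with columns ``dose``, ``cell_id`` and
    one column per recorded species; all intensities are strictly positive
    (lognormal support).
    """

    data: pd.DataFrame
    species: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ("dose", "cell_id", *self.species) if c not in self.data.columns]
        if missing:
            raise InputError(f"dataset table missing columns: {missing}")
        vals = self.data[self.species].to_numpy()
        if not np.all(vals > 0):
            raise InputError("all intensities must be strictly positive")

    @property
    def doses(self) -> np.ndarray:
        return np.unique(self.data["dose"].to_numpy())

    def ensemble(self, dose: float) -> pd.DataFrame:
        """The (n_cells, species) intensity block at one dose."""
        block = self.data.loc[self.data["dose"] == dose, self.species]
        if block.empty:
            raise InputError(f"no cells recorded at dose {dose}")
        return block


def _resolve_path(m: MotifSpec, d: DoseDesign) -> VarCovPath:
    return motif_trajectory(m, d.doses, d.dose_map(m))


def simulate_ensemble(
    m: MotifSpec,
    d: DoseDesign,
    record: str = "measured",
    meas_log_sd: float = 0.0,
) -> DoseDataset:
    """Draw stationary per-dose ensembles from the linearized motif.

    At each dose the motif is linearized, the Lyapunov equation solved,
    and ``n_cells`` independent log-deviation vectors drawn from the
    zero-mean multivariate normal with that stationary covariance; adding
    the log-scale means and exponentiating yields exactly-lognormal
    marginal intensities.  ``record`` selects ``"measured"`` (nodes 1 and
    2, emulating a two-channel assay) or ``"all"`` nodes.  Optional
    multiplicative measurement noise (an independent lognormal factor per
    cell and species with log-sd ``meas_log_sd``) is off by default.

    One master seed deterministically spawns independent per-dose
    streams, so datasets are reproducible and parallel-safe.
    """
    if record not in ("measured", "all"):
        raise InputError(f"record must be 'measured' or 'all', got {record!r}")
    path = _resolve_path(m, d)
    idx = list(MEASURED) if record == "measured" else list(range(m.n_nodes))
    species = [m.labels[i] for i in idx]
    streams = np.random.SeedSequence(d.seed).spawn(len(path.points))
    frames = []
    for pt, ss in zip(path.points, streams):
        rng = np.random.default_rng(ss)
        cov = pt.sigma_full.Sigma0[np.ix_(idx, idx)]
        mu = np.log(pt.means[idx])
        try:
            dev = rng.multivariate_normal(np.zeros(len(idx)), cov, size=d.n_cells,
                                          method="cholesky")
        except np.linalg.LinAlgError:
            # semidefinite covariance (a noiseless node): fall back to SVD
            dev = rng.multivariate_normal(np.zeros(len(idx)), cov, size=d.n_cells,
                                          method="svd")
        logs = mu + dev
        if meas_log_sd > 0:
            logs = logs + rng.normal(0.0, meas_log_sd, size=logs.shape)
        block = pd.DataFrame(np.exp(logs), columns=species)
        block.insert(0, "cell_id", np.arange(d.n_cells))
        block.insert(0, "dose", pt.dose)
        frames.append(block)
    data = pd.concat(frames, ignore_index=True)
    meta = {
        "motif": m.to_dict(),
        "seed": int(d.seed),
        "n_cells": int(d.n_cells),
        "doses": np.asarray(d.doses).tolist(),
        "record": record,
        "meas_log_sd": float(meas_log_sd),
        "true_direction": _true_direction(m, species),
    }
    return DoseDataset(data=data, species=species, metadata=meta)


def _true_direction(m: MotifSpec, species: list[str]) -> list[str] | None:
    """Ground-truth directed edge among the measured pair, if present."""
    for (s, t) in m.edges:
        if m.labels[s] in species and m.labels[t] in species:
            return [m.labels[s], m.labels[t]]
    return None


def _check_dt(m: MotifSpec, A: np.ndarray, dt: float) -> None:
    max_rate = max(float(np.max(np.abs(A))), float(np.max(m.lambdas)))
    if dt >= 0.1 / max_rate:
        raise InputError(
            f"dt={dt} too large for fastest rate {max_rate:.3g}; need dt < {0.1 / max_rate:.3g}"
        )


def simulate_sde(
    m: MotifSpec,
    dose: float,
    n_cells: int,
    t_end: float,
    dt: float,
    seed: int,
    dose_map: Callable[[float], dict[int, float]] | None = None,
    drive: object = None,
    record: str = "measured",
) -> pd.DataFrame:
    """Euler--Maruyama ensemble snapshot of the log-deviation dynamics.

    Integrates dδy = A δy dt + Q dW for ``n_cells`` independent cells from
    the fixed point and returns the terminal snapshot in linear scale.
    ``t_end`` should exceed ~10/min(λ) so the ensemble has relaxed to
    stationarity.
    """
    if dose_map is None:
        if drive is None:
            raise InputError("supply dose_map or drive")
        dose_map = DoseDesign(doses=[dose], upstream_drive=drive).dose_map(m)
    model, x = linearize_at(m, dose_map(dose))
    _check_dt(m, model.A, dt)
    rng = np.random.default_rng(seed)
    n_steps = int(np.ceil(t_end / dt))
    A, Q = model.A, model.Q
    y = np.zeros((n_cells, m.n_nodes))
    sqdt = np.sqrt(dt)
    for _ in range(n_steps):
        noise = rng.standard_normal((n_cells, Q.shape[1]))
        y = y + y @ A.T * dt + noise @ Q.T * sqdt
    idx = list(MEASURED) if record == "measured" else list(range(m.n_nodes))
    species = [m.labels[i] for i in idx]
    out = pd.DataFrame(np.exp(np.log(x[idx]) + y[:, idx]), columns=species)
    out.insert(0, "cell_id", np.arange(n_cells))
    out.insert(0, "dose", float(dose))
    return out


def sde_trajectory(
    m: MotifSpec,
    dose: float,
    t_end: float,
    dt: float,
    seed: int,
    dose_map: Callable[[float], dict[int, float]] | None = None,
    drive: object = None,
) -> np.ndarray:
    """Single-cell log-deviation trajectory, shape (n_steps + 1, n_nodes).

    Used for ergodic cross-checks: time statistics of one long trajectory
    versus ensemble statistics of many cells, and empirical lagged
    covariances versus Σ(τ) = Σ₀ exp(Aᵀτ).
    """
    if dose_map is None:
        if drive is None:
            raise InputError("supply dose_map or drive")
        dose_map = DoseDesign(doses=[dose], upstream_drive=drive).dose_map(m)
    model, _ = linearize_at(m, dose_map(dose))
    _check_dt(m, model.A, dt)
    rng = np.random.default_rng(seed)
    n_steps = int(np.ceil(t_end / dt))
    A, Q = model.A, model.Q
    path = np.empty((n_steps + 1, m.n_nodes))
    y = np.zeros(m.n_nodes)
    path[0] = y
    sqdt = np.sqrt(dt)
    noise = rng.standard_normal((n_steps, Q.shape[1]))
    for i in range(n_steps):
        y = y + A @ y * dt + Q @ noise[i] * sqdt
        path[i + 1] = y
    return path


def analytic_covariances(m: MotifSpec, d: DoseDesign) -> VarCovPath:
    """The generator's ground-truth covariance path for a design (oracle)."""
    return _resolve_path(m, d)


# -- persistence ---------------------------------------------------------


def write_dataset(ds: DoseDataset, path) -> tuple[Path, Path]:
    """Write the event table as CSV plus a JSON metadata sidecar.

    Intensities are written with full double precision so the round trip
    through :func:`read_dataset` is lossless.
    """
    csv_path = Path(path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    meta_path = csv_path.with_suffix(csv_path.suffix + ".meta.json")
    ds.data.to_csv(csv_path, index=False, float_format="%.17g")
    with open(meta_path, "w") as fh:
        json.dump({"species": ds.species, "metadata": ds.metadata}, fh, indent=2)
    return csv_path, meta_path


def read_dataset(path) -> DoseDataset:
    """Read a dataset written by :func:`write_dataset` (sidecar optional).

    Without a sidecar, every non-``dose``/``cell_id`` column is taken as a
    species channel — this covers plain exported cytometry event tables.
    """
    csv_path = Path(path)
    try:
        data = pd.read_csv(csv_path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise ParseError(f"cannot read event table {csv_path}: {e}") from e
    if data.empty:
        raise ParseError(f"event table {csv_path} contains no rows")
    if "dose" not in data.columns:
        raise ParseError(f"event table {csv_path} lacks a 'dose' column")
    if "cell_id" not in data.columns:
        data.insert(1, "cell_id", data.groupby("dose").cumcount())
    meta_path = csv_path.with_suffix(csv_path.suffix + ".meta.json")
    species: list[str]
    metadata: dict = {}
    if meta_path.exists():
        try:
            with open(meta_path) as fh:
                side = json.load(fh)
            species = list(side["species"])
            metadata = dict(side.get("metadata", {}))
        except (json.JSONDecodeError, KeyError) as e:
            raise ParseError(f"malformed sidecar {meta_path}: {e}") from e
    else:
        species = [c for c in data.columns if c not in ("dose", "cell_id")]
    return DoseDataset(data=data, species=species, metadata=metadata)
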