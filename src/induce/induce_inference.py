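"""Estimation pipeline: normalization, per-dose covariance, two-node model fit.

The pipeline mirrors the graphical analysis of a dose-response
experiment on a putatively causal species pair:

1. fit Hill dose-response curves to each species' per-dose mean
   (log-coordinate least squares) to obtain normalization constants and
   the transfer-function slope sign (activation vs repression);
2. normalize intensities in linear scale (source by its half-response
   constant K̂, responding species by its response amplitude ν̂) and take
   natural logs — a pure shift in log coordinates, so covariances are
   unaffected;
3. per dose, estimate the bivariate-normal ML mean and covariance of the
   log intensities and bootstrap the covariance elements' standard
   deviations (cells resampled with replacement within dose);
4. fit the isolated-edge model in a specified direction: source variance
   constant at α, target variance β + 2σ₁₂²/α, by joint least squares
   over doses.

Comparing the fit of the two directed models is done in
:mod:`induce.causation_stats`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from induce.errors import FitError, InputError, InsufficientDataError
from induce.motif_models import ConstantTransfer, HillTransfer, hill_response
from induce.synthetic_data import DoseDataset


@dataclass
class NormalizationParams:
    """Per-species linear-scale normalization constants from Hill fits.

    ``scales`` holds the divisor actually applied to each species (K̂ for
    the source, ν̂ for responding species).
    """

    K: dict[str, float]
    nu: dict[str, float]
    scales: dict[str, float]
    slope_sign: int = 0          # sign of target-vs-source transfer slope
    degenerate: bool = False     # flat target response (k ≈ 0 everywhere)

    def __post_init__(self) -> None:
        for name, v in list(self.K.items()) + list(self.nu.items()):
            if v <= 0:
                raise InputError(f"normalization constant for {name} must be positive")


@dataclass
class FittedCovariance:
    """Per-dose bivariate-normal ML estimate with bootstrap uncertainties."""

    dose: float
    species: tuple[str, str]
    mean: np.ndarray
    var1: float
    var2: float
    cov12: float
    n_cells: int
    sd_var1: float = np.nan
    sd_var2: float = np.nan
    sd_cov12: float = np.nan

    def __post_init__(self) -> None:
        if self.var1 < 0 or self.var2 < 0:
            raise InputError("variances must be nonnegative")
        bound = np.sqrt(self.var1 * self.var2)
        if abs(self.cov12) > bound * (1 + 1e-12) + 1e-300:
            raise InputError("covariance violates Cauchy-Schwarz bound")

    def var(self, name: str) -> float:
        return self.var1 if name == self.species[0] else self.var2

    def sd_var(self, name: str) -> float:
        return self.sd_var1 if name == self.species[0] else self.sd_var2


@dataclass
class TwoNodeFit:
    """Directed isolated-edge fit over doses."""

    direction: tuple[str, str]
    alpha_hat: float
    beta_hat: float
    c_hat: float
    doses: np.ndarray
    pred_source_var: np.ndarray
    pred_target_var: np.ndarray
    errors: np.ndarray           # per-dose ε_i, squared-error units
    total_error: float
    boundary_warning: bool = False

    def predicted_vars(self, i: int) -> tuple[float, float]:
        """(source, target) predicted variances at dose index ``i``."""
        return float(self.pred_source_var[i]), float(self.pred_target_var[i])


# -- transfer-function fitting ------------------------------------------


def _fit_hill_log(doses: np.ndarray, mean_logs: np.ndarray,
                  repression: bool) -> HillTransfer:
    """Least-squares Hill fit of dose-wise mean log intensity vs dose."""
    lin = np.exp(mean_logs)
    nu0 = float(np.max(lin)) * (1.05 if repression else 1.05)
    half = nu0 / 2.0
    # dose whose response is nearest half-maximal as K start
    K0 = float(doses[np.argmin(np.abs(lin - half))])
    K0 = max(K0, float(np.min(doses)) * 0.5)
    theta0 = np.log([nu0, K0, 1.0])

    def resid(theta):
        nu, K, n = np.exp(theta)
        h = HillTransfer(nu=nu, K=K, n=n, repression=repression)
        return np.log(hill_response(doses, h)) - mean_logs

    sol = optimize.least_squares(resid, theta0, method="lm", max_nfev=10_000)
    if not sol.success:
        sol = optimize.least_squares(resid, theta0, method="trf", max_nfev=10_000)
    if not sol.success:
        raise FitError(
            f"Hill fit failed: {sol.message}; starts nu={nu0:.3g}, K={K0:.3g}"
        )
    nu, K, n = np.exp(sol.x)
    return HillTransfer(nu=float(nu), K=float(K), n=float(n), repression=repression)


def fit_transfer(
    ds: DoseDataset, source: str, target: str,
    degenerate_amplitude: float = 0.05,
) -> tuple[dict[str, HillTransfer], NormalizationParams]:
    """Hill dose-response fits for both species plus normalization constants.

    Fits are log-coordinate least squares on the dose-wise mean log
    intensities; doses ≤ 0 are excluded from the curve fit (the Hill form
    is only defined for positive dose).  The sign of the target-vs-source
    transfer slope is recorded as the activation/repression call; a target
    whose mean-log dynamic range is below ``degenerate_amplitude`` is
    flagged degenerate (no usable connection-strength sweep).
    """
    doses_all = ds.doses
    if len(doses_all) < 5:
        raise InsufficientDataError(
            f"transfer fitting needs >= 5 doses, got {len(doses_all)}"
        )
    pos = doses_all[doses_all > 0]
    mean_logs = {
        sp: np.array([np.log(ds.ensemble(d)[sp]).mean() for d in pos])
        for sp in (source, target)
    }
    hills: dict[str, object] = {}
    K_hat: dict[str, float] = {}
    nu_hat: dict[str, float] = {}
    for sp in (source, target):
        if float(np.ptp(mean_logs[sp])) < degenerate_amplitude:
            # flat response: Hill parameters unidentifiable; normalize by
            # the geometric-mean level instead (a pure log shift anyway)
            level = float(np.exp(np.mean(mean_logs[sp])))
            hills[sp] = ConstantTransfer(level=level)
            K_hat[sp] = nu_hat[sp] = level
            continue
        rho = stats.spearmanr(pos, mean_logs[sp]).statistic
        repression = bool(rho < 0)
        h = _fit_hill_log(pos, mean_logs[sp], repression)
        hills[sp] = h
        K_hat[sp], nu_hat[sp] = h.K, h.nu
    # transfer slope: regression of target mean log on source mean log
    slope = np.polyfit(mean_logs[source], mean_logs[target], 1)[0]
    target_range = float(np.ptp(mean_logs[target]))
    degenerate = target_range < degenerate_amplitude
    if degenerate:
        warnings.warn(
            f"target {target} mean-log dynamic range {target_range:.3g} below "
            f"{degenerate_amplitude}; transfer is effectively flat", stacklevel=2)
    params = NormalizationParams(
        K=K_hat,
        nu=nu_hat,
        scales={source: K_hat[source], target: nu_hat[target]},
        slope_sign=0 if degenerate else int(np.sign(slope)),
        degenerate=degenerate,
    )
    return hills, params


def normalize(
    ds: DoseDataset, p: NormalizationParams, drop_threshold: float = 0.0,
) -> pd.DataFrame:
    """Linear-scale normalization followed by natural log.

    Returns a long table (dose, cell_id, species columns) of
    log-normalized intensities.  Cells with any intensity ≤
    ``drop_threshold`` are dropped (count reported via a warning) since
    the log transform requires positive support; this mirrors standard
    cytometry positivity gating.
    """
    species = [sp for sp in ds.species if sp in p.scales]
    vals = ds.data[species].to_numpy(dtype=float)
    keep = np.all(vals > drop_threshold, axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} cells with intensities <= {drop_threshold}",
                      stacklevel=2)
    out = ds.data.loc[keep, ["dose", "cell_id"]].copy()
    scales = np.array([p.scales[sp] for sp in species])
    out[species] = np.log(vals[keep] / scales)
    return out.reset_index(drop=True)


# -- covariance estimation ----------------------------------------------


def _ml_cov(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    dev = x - mu
    return mu, dev.T @ dev / x.shape[0]


def estimate_covariance(
    logs: pd.DataFrame | np.ndarray,
    species: tuple[str, str],
    dose: float = np.nan,
    min_cells: int = 10,
) -> FittedCovariance:
    """Bivariate-normal ML fit (sample mean, covariance with denominator n)."""
    x = (logs[list(species)].to_numpy(dtype=float)
         if isinstance(logs, pd.DataFrame) else np.asarray(logs, dtype=float))
    if x.shape[0] < max(min_cells, 2):
        raise InsufficientDataError(
            f"covariance estimation needs >= {max(min_cells, 2)} cells, got {x.shape[0]}"
        )
    mu, S = _ml_cov(x)
    return FittedCovariance(
        dose=float(dose), species=tuple(species), mean=mu,
        var1=float(S[0, 0]), var2=float(S[1, 1]), cov12=float(S[0, 1]),
        n_cells=int(x.shape[0]),
    )


def bootstrap_covariance(
    logs: pd.DataFrame | np.ndarray,
    species: tuple[str, str],
    B: int = 1000,
    seed: int = 0,
    chunk: int = 200,
) -> dict[str, float]:
    """Bootstrap SDs of the covariance elements (resampling cells within dose)."""
    if B < 100:
        raise InputError(f"bootstrap needs B >= 100, got {B}")
    x = (logs[list(species)].to_numpy(dtype=float)
         if isinstance(logs, pd.DataFrame) else np.asarray(logs, dtype=float))
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    stats_ = np.empty((B, 3))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        idx = rng.integers(0, n, size=(b, n))
        xs = x[idx]                                  # (b, n, 2)
        mu = xs.mean(axis=1, keepdims=True)
        dev = xs - mu
        stats_[done:done + b, 0] = np.einsum("bij,bij->b", dev[..., :1], dev[..., :1]) / n
        stats_[done:done + b, 1] = np.einsum("bij,bij->b", dev[..., 1:], dev[..., 1:]) / n
        stats_[done:done + b, 2] = np.einsum("bi,bi->b", dev[..., 0], dev[..., 1]) / n
        done += b
    sd = stats_.std(axis=0, ddof=1)
    return {"sd_var1": float(sd[0]), "sd_var2": float(sd[1]), "sd_cov12": float(sd[2])}


def covariance_by_dose(
    logs: pd.DataFrame,
    species: tuple[str, str],
    bootstrap: int = 0,
    seed: int = 0,
) -> list[FittedCovariance]:
    """Per-dose ML covariance estimates, optionally with bootstrap SDs."""
    out: list[FittedCovariance] = []
    streams = np.random.SeedSequence(seed).spawn(logs["dose"].nunique())
    for ss, (dose, block) in zip(streams, logs.groupby("dose", sort=True)):
        fc = estimate_covariance(block, species, dose=float(dose))
        if bootstrap:
            sds = bootstrap_covariance(block, species, B=bootstrap,
                                       seed=int(ss.generate_state(1)[0] % (2**31)))
            fc.sd_var1, fc.sd_var2, fc.sd_cov12 = (
                sds["sd_var1"], sds["sd_var2"], sds["sd_cov12"])
        out.append(fc)
    return out


# -- directed two-node model fit ----------------------------------------


def fit_two_node(
    fcs: list[FittedCovariance],
    direction: tuple[str, str],
    third_param: bool = False,
    weighted: bool = False,
) -> TwoNodeFit:
    """Joint least-squares fit of the isolated-edge covariance law.

    In the hypothesized direction (source, target) the model constrains
    the source variance to a constant α and the target variance to the
    quadratic β + 2(σ₁₂ − c)²/α; both residuals enter the objective
    jointly.  α > 0 is enforced by log-parameterization; the optional
    third parameter c (a dose-independent covariance offset) defaults to
    off; ``weighted`` switches to inverse-bootstrap-variance weights.
    """
    if len(fcs) < 4:
        raise InsufficientDataError(f"two-node fit needs >= 4 doses, got {len(fcs)}")
    src, tgt = direction
    for fc in fcs:
        if src not in fc.species or tgt not in fc.species:
            raise InputError(f"direction {direction} not in species {fc.species}")
    doses = np.array([fc.dose for fc in fcs])
    v_src = np.array([fc.var(src) for fc in fcs])
    v_tgt = np.array([fc.var(tgt) for fc in fcs])
    s12 = np.array([fc.cov12 for fc in fcs])
    if weighted:
        w_src = np.array([fc.sd_var(src) for fc in fcs]) ** -2.0
        w_tgt = np.array([fc.sd_var(tgt) for fc in fcs]) ** -2.0
        if not (np.all(np.isfinite(w_src)) and np.all(np.isfinite(w_tgt))):
            raise InputError("weighted fit requires finite bootstrap SDs on all doses")
    else:
        w_src = np.ones_like(v_src)
        w_tgt = np.ones_like(v_tgt)

    def unpack(theta):
        alpha = float(np.exp(theta[0]))
        c = float(theta[1]) if third_param else 0.0
        resid_t = v_tgt - 2.0 * (s12 - c) ** 2 / alpha
        beta = float(np.sum(w_tgt * resid_t) / np.sum(w_tgt))
        return alpha, beta, c

    def objective(theta):
        alpha, beta, c = unpack(theta)
        return (np.sum(w_src * (v_src - alpha) ** 2)
                + np.sum(w_tgt * (v_tgt - beta - 2.0 * (s12 - c) ** 2 / alpha) ** 2))

    med = float(np.median(v_src))
    starts = [np.log(max(med, 1e-12))]
    # curvature-based start: regress target variance on σ₁₂² (slope = 2/α)
    slope = np.polyfit(s12 ** 2, v_tgt, 1)[0]
    if slope > 0:
        starts.append(np.log(2.0 / slope))
    best = None
    for s0 in starts:
        theta0 = np.array([s0, 0.0][: (2 if third_param else 1)])
        sol = optimize.minimize(objective, theta0, method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14,
                                         "maxiter": 20_000, "maxfev": 20_000})
        if best is None or sol.fun < best.fun:
            best = sol
    alpha, beta, c = unpack(best.x)
    pred_src = np.full_like(v_src, alpha)
    pred_tgt = beta + 2.0 * (s12 - c) ** 2 / alpha
    errors = (v_src - pred_src) ** 2 + (v_tgt - pred_tgt) ** 2
    boundary = bool(alpha < 1e-10 * max(med, 1e-300))
    if boundary:
        warnings.warn(f"fitted alpha {alpha:.3g} at positivity boundary", stacklevel=2)
    return TwoNodeFit(
        direction=(src, tgt), alpha_hat=alpha, beta_hat=beta, c_hat=c,
        doses=doses, pred_source_var=pred_src, pred_target_var=pred_tgt,
        errors=errors, total_error=float(errors.sum()),
        boundary_warning=boundary,
    )
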