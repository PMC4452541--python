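"""Self-contained validation studies of the inference method.

Each function runs a complete study — generate data under known ground
truth, run the pipeline, measure the outcome — and returns plain
numbers.  They serve as the package's statistical benchmark battery:
direction-discrimination power, null (severed-edge) calibration of the
paired test, the sign rule's accuracy, agreement between the analytic,
closed-form and simulated covariance routes, and the exact signed-rank
floor.  The reference study conditions are those of
:mod:`induce.presets`: 23 log-spaced doses × 10⁴ cells per dose.
"""

from __future__ import annotations

import warnings

import numpy as np

from induce.causation_stats import run_induce, wilcoxon_signed_rank
from induce.induce_inference import NormalizationParams, covariance_by_dose, fit_two_node, normalize
from induce.langevin_core import NetworkModel, solve_lyapunov
from induce.motif_models import (
    TwoNodeNoiseParams,
    motif_trajectory,
    two_node_covariance,
    var2_of_cov,
)
from induce.presets import example_design
from induce.synthetic_data import analytic_covariances, sde_trajectory, simulate_ensemble, simulate_sde

_PIPE = {"bootstrap": 0, "seed": 1}


def _child_seeds(seed: int, n: int) -> list[int]:
    states = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % 2**31) for s in states]


def wilcoxon_floor_p(n: int = 23) -> float:
    """Exact one-sided signed-rank p when one model wins at every dose.

    This is the smallest p attainable with ``n`` pairs (2⁻ⁿ), the value a
    uniformly favorable paired comparison reports.
    """
    d = np.arange(1, n + 1, dtype=float)
    return wilcoxon_signed_rank(d, sided="greater")["p"]


def closed_form_vs_lyapunov(n_draws: int = 1000, seed: int = 0) -> float:
    """Max relative deviation between the isolated-edge closed form and the
    numeric Lyapunov solution over random parameter draws."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        alpha = rng.uniform(0.01, 10.0)
        beta = rng.uniform(0.0, 10.0)
        lam = rng.uniform(0.05, 10.0)
        k = rng.uniform(-10.0, 10.0)
        S_cf = two_node_covariance(TwoNodeNoiseParams(alpha, beta, lam, k)).Sigma0
        model = NetworkModel(A=[[-lam, 0.0], [k, -lam]],
                             Q=np.diag(np.sqrt([2 * lam * alpha, 2 * lam * beta])))
        S_num = solve_lyapunov(model).Sigma0
        dev = np.max(np.abs(S_cf - S_num)) / np.max(np.abs(S_num))
        worst = max(worst, float(dev))
    return worst


def quadratic_law_analytic(preset: str = "two_node_activation") -> dict[str, float]:
    """Exactness of the variance-covariance law on the analytic path.

    Returns the relative spread of the source variance and the maximum
    relative deviation of the target variance from β + 2σ₁₂²/α along the
    default dose sweep.
    """
    m, d = example_design(preset, n_cells=2)
    s12, s11, s22 = analytic_covariances(m, d).series()
    alpha = float(m.qs[0] ** 2 / (2 * m.lambdas[0]))
    beta = float(m.qs[1] ** 2 / (2 * m.lambdas[1]))
    spread = float(np.ptp(s11) / np.abs(s11).max())
    dev = float(np.max(np.abs(s22 - var2_of_cov(s12, alpha, beta))
                       / np.abs(s22).max()))
    return {"source_var_rel_spread": spread, "target_var_law_rel_dev": dev}


def two_node_recovery(seed: int = 0, n_cells: int = 10_000) -> dict[str, float]:
    """Relative errors of α̂, β̂ on one sampled activation dataset."""
    m, d = example_design("two_node_activation", n_cells=n_cells, seed=seed)
    ds = simulate_ensemble(m, d)
    unit = NormalizationParams(K={"y1": 1.0, "y2": 1.0},
                               nu={"y1": 1.0, "y2": 1.0},
                               scales={"y1": 1.0, "y2": 1.0})
    fcs = covariance_by_dose(normalize(ds, unit), ("y1", "y2"))
    fit = fit_two_node(fcs, ("y1", "y2"))
    alpha = float(m.qs[0] ** 2 / (2 * m.lambdas[0]))
    beta = float(m.qs[1] ** 2 / (2 * m.lambdas[1]))
    return {
        "alpha_rel_error": abs(fit.alpha_hat - alpha) / alpha,
        "beta_rel_error": abs(fit.beta_hat - beta) / beta,
    }


def direction_discrimination(n_runs: int = 200, seed: int = 0,
                             n_cells: int = 10_000) -> dict[str, float]:
    """Power study: fraction of directed datasets where the forward model
    both has the smaller total fit error and wins at one-sided p ≤ 0.05."""
    wins = 0
    smaller_forward = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in _child_seeds(seed, n_runs):
            m, d = example_design("two_node_activation", n_cells=n_cells, seed=s)
            ds = simulate_ensemble(m, d)
            res, rep = run_induce(ds, "y1", "y2", _PIPE)
            fwd_smaller = (rep["fit_forward"].total_error
                           < rep["fit_reverse"].total_error)
            smaller_forward += fwd_smaller
            wins += (fwd_smaller and res.favored == ("y1", "y2")
                     and res.one_sided_p <= 0.05)
    return {"power": wins / n_runs,
            "forward_error_smaller_rate": smaller_forward / n_runs,
            "n_runs": n_runs}


def type_i_error(n_runs: int = 1000, seed: int = 0,
                 n_cells: int = 10_000) -> dict[str, float]:
    """Severed-edge calibration: how often a direction is (falsely) called
    at the default α = 0.05 on k = 0 data."""
    calls = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in _child_seeds(seed + 1, n_runs):
            m, d = example_design("two_node_null", n_cells=n_cells, seed=s)
            ds = simulate_ensemble(m, d)
            res, _ = run_induce(ds, "y1", "y2", _PIPE)
            calls += res.favored is not None
    return {"type_i_rate": calls / n_runs, "n_runs": n_runs}


def sign_rule_accuracy(n_seeds: int = 50, seed: int = 0,
                       n_cells: int = 10_000) -> dict[str, float]:
    """Fraction of activating/repressive datasets whose aggregate fitted
    σ̂₁₂ has the true sign and whose regulation call is correct."""
    correct = {"activation": 0, "repression": 0}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for kind, preset in (("activation", "two_node_activation"),
                             ("repression", "two_node_repression")):
            for s in _child_seeds(seed + 2, n_seeds):
                m, d = example_design(preset, n_cells=n_cells, seed=s)
                ds = simulate_ensemble(m, d)
                res, rep = run_induce(ds, "y1", "y2", _PIPE)
                covs = rep["covariances"]["cov12"].to_numpy()
                sign_ok = (covs.sum() > 0) if kind == "activation" else (covs.sum() < 0)
                correct[kind] += sign_ok and res.regulation == kind
    return {"activation_call_rate": correct["activation"] / n_seeds,
            "repression_call_rate": correct["repression"] / n_seeds,
            "n_seeds": n_seeds}


def sde_consistency(seed: int = 0, n_cells: int = 20_000, dt: float = 0.005,
                    t_end: float = 12.0) -> dict[str, float]:
    """Cross-validation of the two sampling routes against the theory.

    Returns the maximum relative deviation of the SDE-ensemble stationary
    covariance from the Lyapunov solution (over a low/mid/high dose
    triplet) and the agreement of one long trajectory's temporal
    covariance with the population covariance (ergodicity).
    """
    m, d = example_design("two_node_activation")
    dm = d.dose_map(m)
    doses = [float(d.doses[3]), float(d.doses[11]), float(d.doses[19])]
    seeds = _child_seeds(seed + 3, len(doses) + 1)
    worst = 0.0
    for dose, s in zip(doses, seeds):
        snap = simulate_sde(m, dose, n_cells=n_cells, t_end=t_end, dt=dt,
                            seed=s, dose_map=dm)
        emp = np.cov(np.log(snap[["y1", "y2"]].to_numpy()).T, ddof=0)
        truth = motif_trajectory(m, [dose], dm).points[0].sigma.Sigma0
        worst = max(worst, float(np.max(np.abs(emp - truth))
                                 / np.max(np.abs(truth))))
    # ergodicity: temporal covariance of one long trajectory
    dose = doses[1]
    traj = sde_trajectory(m, dose, t_end=4000.0, dt=0.01, seed=seeds[-1],
                          dose_map=dm)
    y = traj[int(20.0 / 0.01):, :2]
    truth = motif_trajectory(m, [dose], dm).points[0].sigma.Sigma0
    temporal = np.cov(y.T, ddof=0)
    ergodic_dev = float(np.max(np.abs(temporal - truth)) / np.max(np.abs(truth)))
    return {"sde_cov_max_rel_dev": worst, "ergodic_cov_rel_dev": ergodic_dev}
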