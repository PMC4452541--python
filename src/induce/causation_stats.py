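"""Statistical test for causal direction from paired per-dose fit errors.

Two directed isolated-edge models are fitted to the same per-dose
covariance elements: model 1 (source → target) and model 2 (target →
source).  Each model's fit quality at dose i is summarized by

    ε_i = [Var(species1)_actual − Var(species1)_model]²
        + [Var(species2)_actual − Var(species2)_model]²,

and because both models are scored on identical doses, the comparison is
paired.  A Wilcoxon signed-rank test on d_i = ε_i^M2 − ε_i^M1 tests the
null that the two models fit equally well; if rejected, the model with
consistently smaller errors is favored and its confidence quantified by
the one-sided signed-rank p-value.  For N ≤ 25 the null distribution is
enumerated exactly (the minimum attainable one-sided p at N pairs is
2⁻ᴺ); above that a normal approximation with continuity and tie
corrections is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from induce.errors import InputError
from induce.induce_inference import (
    FittedCovariance,
    TwoNodeFit,
    covariance_by_dose,
    fit_transfer,
    fit_two_node,
    normalize,
)
from induce.synthetic_data import DoseDataset

#: largest N for which the exact null enumeration is used
EXACT_N_MAX = 25


@dataclass
class ModelErrors:
    """Paired per-dose fit errors of the two directed models."""

    doses: np.ndarray
    eps_model1: np.ndarray
    eps_model2: np.ndarray
    model1: tuple[str, str] = ("", "")
    model2: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.eps_model1 = np.asarray(self.eps_model1, dtype=float)
        self.eps_model2 = np.asarray(self.eps_model2, dtype=float)
        if not (len(self.doses) == len(self.eps_model1) == len(self.eps_model2)):
            raise InputError("paired comparison requires equal-length error vectors")
        if np.any(self.eps_model1 < 0) or np.any(self.eps_model2 < 0):
            raise InputError("fit errors are sums of squares and must be nonnegative")

    @property
    def N(self) -> int:
        return len(self.doses)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dose": self.doses,
            "eps_model1": self.eps_model1,
            "eps_model2": self.eps_model2,
        })


@dataclass
class CausationResult:
    """Outcome of the paired direction comparison."""

    favored: tuple[str, str] | None
    one_sided_p: float
    two_sided_p: float
    N: int
    regulation: str | None = None      # "activation" | "repression" | None
    n_zero_differences: int = 0
    errors: ModelErrors | None = None
    details: dict = field(default_factory=dict)


def fit_error(actual: FittedCovariance, fit: TwoNodeFit, dose_index: int) -> float:
    """Per-dose squared fit error: sum over both species of (ΔVar)²."""
    if not np.isclose(actual.dose, fit.doses[dose_index]):
        raise InputError(
            f"dose mismatch: actual {actual.dose} vs fit {fit.doses[dose_index]}"
        )
    src, tgt = fit.direction
    pred_src, pred_tgt = fit.predicted_vars(dose_index)
    return float((actual.var(src) - pred_src) ** 2 + (actual.var(tgt) - pred_tgt) ** 2)


def model_errors(
    fcs: list[FittedCovariance], fit1: TwoNodeFit, fit2: TwoNodeFit
) -> ModelErrors:
    """Assemble the paired error table for two directed fits on shared doses."""
    if not np.allclose(fit1.doses, fit2.doses):
        raise InputError("the two models were not fitted on identical dose sets")
    e1 = np.array([fit_error(fc, fit1, i) for i, fc in enumerate(fcs)])
    e2 = np.array([fit_error(fc, fit2, i) for i, fc in enumerate(fcs)])
    return ModelErrors(doses=fit1.doses, eps_model1=e1, eps_model2=e2,
                       model1=fit1.direction, model2=fit2.direction)


# -- Wilcoxon signed-rank test ------------------------------------------


def _signed_rank_statistic(d: np.ndarray) -> tuple[float, np.ndarray, int]:
    """(W⁺, average ranks of |d|, number of zero differences dropped)."""
    d = np.asarray(d, dtype=float)
    nz = d[d != 0]
    n_zero = int(len(d) - len(nz))
    if len(nz) == 0:
        return 0.0, np.array([]), n_zero
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    return w_plus, ranks, n_zero


def _exact_null_counts(ranks: np.ndarray) -> np.ndarray:
    """Counts of W⁺ values over all 2ⁿ sign assignments.

    Ranks are doubled so average ranks (which end in .5 under ties)
    become integers; index i of the returned array counts assignments
    with 2·W⁺ = i.  Built by polynomial multiplication of (1 + z^(2r))
    over the ranks — O(n · n²) work, trivial for n ≤ 25.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    counts = np.zeros(int(r2.sum()) + 1, dtype=np.float64)
    counts[0] = 1.0
    top = 0
    for r in r2:
        nxt = counts.copy()
        nxt[r:top + r + 1] += counts[:top + 1]
        counts = nxt
        top += int(r)
    return counts


def wilcoxon_signed_rank(d, sided: str = "two-sided") -> dict:
    """Wilcoxon signed-rank test of paired differences ``d``.

    Zero differences are dropped (their count is reported); ties among
    |d| receive average ranks.  For N ≤ 25 (after zero removal) the null
    distribution of W⁺ is enumerated exactly over all 2ᴺ sign
    assignments; above that a normal approximation with continuity
    correction and tie-corrected variance is used.  ``sided`` is one of
    ``"greater"`` (alternative: d tends positive), ``"less"``, or
    ``"two-sided"``.  Returns a dict with p, W⁺, n (pairs used), zeros,
    and the method applied.
    """
    if sided not in ("greater", "less", "two-sided"):
        raise InputError(f"sided must be greater/less/two-sided, got {sided!r}")
    w_plus, ranks, n_zero = _signed_rank_statistic(np.asarray(d, dtype=float))
    n = len(ranks)
    if n == 0:
        warnings.warn("all paired differences are zero; test is degenerate",
                      stacklevel=2)
        return {"p": 1.0, "W_plus": 0.0, "n": 0, "zeros": n_zero,
                "method": "degenerate"}
    w_total = float(ranks.sum())
    if n <= EXACT_N_MAX:
        counts = _exact_null_counts(ranks)
        total = 2.0 ** n
        w2 = int(np.rint(2.0 * w_plus))
        p_ge = counts[w2:].sum() / total          # P(W+ >= observed)
        p_le = counts[: w2 + 1].sum() / total     # P(W+ <= observed)
        method = "exact"
    else:
        mu = w_total / 2.0
        tie_counts = np.unique(ranks, return_counts=True)[1]
        var = (n * (n + 1) * (2 * n + 1) / 24.0
               - np.sum(tie_counts ** 3 - tie_counts) / 48.0)
        sd = np.sqrt(var)
        p_ge = float(stats.norm.sf((w_plus - 0.5 - mu) / sd))
        p_le = float(stats.norm.cdf((w_plus + 0.5 - mu) / sd))
        method = "normal-approx"
    if sided == "greater":
        p = p_ge
    elif sided == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return {"p": float(min(p, 1.0)), "W_plus": w_plus, "n": n,
            "zeros": n_zero, "method": method}


# -- direction comparison ------------------------------------------------


def compare_directions(
    e: ModelErrors, alpha: float = 0.05, regulation: str | None = None,
) -> CausationResult:
    """Paired two-stage test of the two directed models.

    Stage 1 tests the null that the models have statistically similar
    fitting errors (two-sided signed-rank on d_i = ε_i^M2 − ε_i^M1 at
    level ``alpha``).  If rejected, the model with consistently smaller
    errors is favored and its one-sided p reported; otherwise no
    direction is called.
    """
    d = e.eps_model2 - e.eps_model1
    two = wilcoxon_signed_rank(d, sided="two-sided")
    w_plus, ranks, _ = _signed_rank_statistic(d)
    mid = float(ranks.sum()) / 2.0 if len(ranks) else 0.0
    model1_better = w_plus > mid      # positive d: model 1 has smaller error
    if two["method"] == "degenerate" or two["p"] >= alpha:
        one = wilcoxon_signed_rank(
            d, sided="greater" if model1_better else "less")
        return CausationResult(
            favored=None, one_sided_p=one["p"], two_sided_p=two["p"],
            N=e.N, regulation=regulation, n_zero_differences=two["zeros"],
            errors=e, details={"alpha": alpha, "method": two["method"],
                               "W_plus": two["W_plus"]},
        )
    sided = "greater" if model1_better else "less"
    one = wilcoxon_signed_rank(d, sided=sided)
    favored = e.model1 if model1_better else e.model2
    return CausationResult(
        favored=favored, one_sided_p=one["p"], two_sided_p=two["p"],
        N=e.N, regulation=regulation, n_zero_differences=one["zeros"],
        errors=e, details={"alpha": alpha, "method": one["method"],
                           "W_plus": one["W_plus"]},
    )


def regulation_sign(fcs: list[FittedCovariance]) -> str | None:
    """Activation/repression call from the covariance sign rule.

    Positive (bootstrap-precision-weighted) aggregate σ̂₁₂ over doses →
    activation; negative → repression; zero → no call.
    """
    covs = np.array([fc.cov12 for fc in fcs])
    sds = np.array([fc.sd_cov12 for fc in fcs])
    w = np.where(np.isfinite(sds) & (sds > 0), sds, np.nan) ** -2.0
    w = np.where(np.isfinite(w), w, 1.0)
    score = float(np.sum(w * covs))
    if score > 0:
        return "activation"
    if score < 0:
        return "repression"
    return None


# -- end-to-end pipeline -------------------------------------------------

DEFAULT_CONFIG = {
    "bootstrap": 1000,
    "seed": 0,
    "alpha": 0.05,
    "third_param": False,
    "weighted": False,
    "drop_threshold": 0.0,
}


def run_induce(
    ds: DoseDataset, source: str, target: str, config: dict | None = None,
) -> tuple[CausationResult, dict]:
    """Full pipeline: transfer fit → normalize → covariances → both directed
    fits → paired error comparison.

    Returns the :class:`CausationResult` plus a report dict with every
    intermediate product (Hill fits, normalization, per-dose covariance
    table, both :class:`TwoNodeFit` objects).  Deterministic under a fixed
    ``config["seed"]``.  Stage failures re-raise with the stage name.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    if len(ds.doses) < 5:
        raise InputError(f"pipeline needs >= 5 doses, got {len(ds.doses)}")

    def stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except Exception as err:
            raise type(err)(f"[stage {name}] {err}") from err

    hills, norm = stage("transfer", fit_transfer, ds, source, target)
    logs = stage("normalize", normalize, ds, norm,
                 drop_threshold=cfg["drop_threshold"])
    fcs = stage("covariance", covariance_by_dose, logs, (source, target),
                bootstrap=cfg["bootstrap"], seed=cfg["seed"])
    fit_fwd = stage("fit-forward", fit_two_node, fcs, (source, target),
                    third_param=cfg["third_param"], weighted=cfg["weighted"])
    fit_rev = stage("fit-reverse", fit_two_node, fcs, (target, source),
                    third_param=cfg["third_param"], weighted=cfg["weighted"])
    errs = stage("errors", model_errors, fcs, fit_fwd, fit_rev)
    result = stage("test", compare_directions, errs, alpha=cfg["alpha"],
                   regulation=regulation_sign(fcs))
    report = {
        "config": cfg,
        "hills": {sp: h.to_dict() for sp, h in hills.items()},
        "normalization": {
            "K": norm.K, "nu": norm.nu, "scales": norm.scales,
            "slope_sign": norm.slope_sign, "degenerate": norm.degenerate,
        },
        "covariances": pd.DataFrame([{
            "dose": fc.dose, "var1": fc.var1, "var2": fc.var2,
            "cov12": fc.cov12, "sd_var1": fc.sd_var1, "sd_var2": fc.sd_var2,
            "sd_cov12": fc.sd_cov12, "n_cells": fc.n_cells,
        } for fc in fcs]),
        "fit_forward": fit_fwd,
        "fit_reverse": fit_rev,
    }
    return result, report
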