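# Methods

## Model

The package models a small network of interacting biomolecular species
(gene products, phosphoproteins) fluctuating around a stable steady
state.  Two empirical facts shape the choice of coordinates: single-cell
concentration distributions are close to lognormal, and fluctuations do
not vanish at high copy number — so the noise is dominated by
multiplicative variation in reaction *rates* rather than by discrete
molecule-number (chemical-Langevin) noise.  We therefore work with the
logarithmic deviation from the mean, δy_j = ln x_j − ⟨ln x_j⟩, whose
linearized dynamics are an Ornstein–Uhlenbeck system

    dδy_j/dt = Σ_{i≠j} a_ji δy_i − λ_j δy_j + q_j ε_j ,

with λ_j the decay (turnover) rate of species j in 1/time, q_j the
magnitude of its intrinsic log-scale white noise, and ε_j independent
unit white noises.  In matrix form dδy = A δy dt + Q dW with
A = −diag(λ) + [a_ji] and Q = diag(q).  The connection strength is the
log-gain of the production function f_ji at the operating point,

    a_ji = λ_j · ∂ln f_ji / ∂ln x_i |_{⟨x_i⟩} ,

with f_ji a Hill function of the *linear-scale* source concentration:
ν x^n/(Kⁿ + xⁿ) for activation, ν Kⁿ/(Kⁿ + xⁿ) for repression.
Analytically the activation gain is λ n Kⁿ/(Kⁿ + xⁿ) ∈ (0, λn] and the
repression gain −λ n xⁿ/(Kⁿ + xⁿ) ∈ [−λn, 0): each is monotone in x and
equals half its supremum exactly at half-maximal activation x = K.
Repression is encoded by the decreasing Hill form with a negative gain,
keeping the Hill coefficient n > 0 in all cases.  A `ConstantTransfer`
(flat production, zero gain) represents a severed edge or a regulator
pinned outside its dynamic range.

At stationarity the covariance Σ₀ of δy satisfies the continuous
Lyapunov equation A Σ₀ + Σ₀ Aᵀ + QQᵀ = 0, and the lagged covariance is
Σ(τ) = Σ₀ e^{Aᵀτ}.  Both are implemented in `langevin_core`, along with
the analytic inverse maps A = (−½QQᵀ + U)Σ₀⁻¹ (U antisymmetric — the
degeneracy that makes a single covariance matrix causally
uninformative) and the thermal-bath case A = −k_BT·Σ₀⁻¹.  For the
thermal case the implied isotropic noise is QQᵀ = 2k_BT·I: the
fluctuation–dissipation factor of two is required for A and Σ₀ to be
mutually consistent with the Lyapunov equation (equivalently, with the
general solution at U = 0).

For an isolated edge 1 → 2 with λ₁ = λ₂ = λ, defining α = q₁²/(2λ) and
β = q₂²/(2λ), the closed form is σ₁² = α, σ₁₂ = αk/(2λ),
σ₂² = β + αk²/(2λ²), hence the single-valued quadratic law
σ₂² = β + 2σ₁₂²/α.  With unequal decay rates the law is still quadratic
but with coefficient (λ₁+λ₂)/λ₂ in place of 2; the fitted model uses the
equal-rate form, and the reference parameterizations share one λ.

## Motif trajectories and open loops

`motif_models` supports three feedback-free motifs over at most three
nodes, of which nodes 1 and 2 are "measured": an isolated edge (1→2),
convergent regulation (1→2 ← 3) and a cascade (3→1→2).  Dose enters
through a drive mapping dose → mean concentration of each root node;
downstream means follow from the rate balance f = λx, solved by damped
fixed-point iteration (damping ½, tolerance 10⁻¹², ≤10⁵ iterations —
geometric convergence for these acyclic motifs).  At each dose the motif
is linearized and the Lyapunov equation solved (dense Bartels–Stewart
via SciPy, residual checked against 10⁻⁸ relative, output symmetrized to
(Σ+Σᵀ)/2 so symmetry is exactly assertable; stability gate: max
eigenvalue real part < −10⁻¹⁰).  When edges converge on one target their
log-deviation contributions are summed per edge, Σ a_ji δy_i, with each
a_ji the log-gain of its own transfer; cross-terms from a shared
production denominator are deliberately not modeled.

Sweeping the dose traces a parametric path of (σ₁₂, σ₁², σ₂²).  The
isolated edge keeps σ₁² constant and σ₂² on the quadratic; a second
noise source with a *different* dose sensitivity can make the path
revisit a covariance value at a different variance — an "open loop",
evidence of an unmeasured upstream species.  The detector fits a
quadratic variance-vs-covariance baseline, then flags point pairs whose
covariances agree within ε_c = 2% of the covariance range while their
variances differ by more than ε_v = 5% of the variance range plus the
baseline scatter (both tolerances configurable; the loop score is the
largest such gap normalized by the variance range).  These defaults are
scale-free and grid-robust; with all-activation edges and a monotone
drive every gain is monotone in dose and no loop can occur, which is why
the shipped looping cascade pairs an activating upstream edge with a
repressive downstream one (opposed gain sweeps).

## Synthetic data

`synthetic_data` generates what the pipeline consumes: per-dose
ensembles of strictly positive linear-scale intensities.  Two routes are
provided and cross-validated:

* **Stationary draw** — exact multivariate-normal sampling of δy from
  the analytic Σ₀ at each dose, exponentiated around the log-scale
  means; marginals are exactly lognormal.  This is the
  ergodic-population route: a snapshot of clonal cells standing in for
  the long-time statistics of one cell.
* **Euler–Maruyama integration** — the temporal route; requires
  dt < 0.1/(fastest rate) and a burn-in ≳ 10/min(λ).  Used to validate
  the stationary solution, the lagged covariance and ergodicity
  end-to-end.

One master seed spawns independent per-dose streams
(`numpy.random.SeedSequence`), so datasets are bit-reproducible and
parallel-safe.  Optional multiplicative measurement noise (independent
lognormal factor per cell and species) is available but off by default,
since the model treats noise amplitudes as dose-independent and
measurement noise is a confounder to probe, not an assumption.

The reference study conditions, used by the presets, the validation
studies and the examples, are 23 log-spaced doses spanning the drive's
dynamic range × 10⁴ cells per dose — the dose count and event scale of
a typical flow-cytometry dose-response experiment — with intrinsic
log-noise magnitudes q of 0.1–0.8 (log-variances of order 10⁻²–10⁻¹,
the coefficient-of-variation range seen for fluorescent reporters).

What the generator does *not* emulate: autofluorescence background and
spectral compensation artifacts, cell-size/cell-cycle structure,
heavy-tailed outliers, debris/doublet events, or dose-dependent noise
amplitudes.  Passing tests therefore demonstrate correctness of the
method under its own model assumptions, not robustness to every
real-cytometry artifact; the positivity filter and the optional
measurement-noise hook are the entry points for probing the latter.

## Estimation pipeline

1. **Transfer fit.**  Per species, dose-wise means of log intensity are
   fitted with a Hill curve by log-coordinate least squares
   (Levenberg–Marquardt on (ln ν, ln K, ln n), with a trust-region
   fallback); doses ≤ 0 are excluded from the curve fit.  The
   activation/repression orientation is seeded by the Spearman sign of
   the mean response.  A species whose mean-log dynamic range is below
   0.05 is treated as flat: its Hill parameters are unidentifiable, so
   normalization falls back to the geometric-mean level and the transfer
   is flagged degenerate.  The sign of the target-vs-source slope is
   recorded as the regulation orientation of the transfer.
2. **Normalization.**  Intensities are divided in linear scale by the
   fitted constants (source by K̂, responding species by ν̂) and natural
   logs are taken.  This is a pure shift in log coordinates — covariance
   elements are provably invariant to it — so it only serves
   comparability across experiments.  Cells with nonpositive intensities
   (possible after instrument compensation) are dropped with a reported
   count; the threshold is configurable.
3. **Per-dose covariance.**  Maximum-likelihood bivariate-normal fit:
   sample mean and covariance with denominator n.  Uncertainties come
   from a within-dose cell bootstrap (default B = 1000, seeded,
   chunked); no outlier trimming is applied.
4. **Directed two-node fit.**  For a hypothesized direction, the model
   constrains the source variance to a constant α and the target
   variance to β + 2(σ₁₂ − c)²/α.  Both residual sets enter one
   least-squares objective; β is profiled out in closed form, α > 0 is
   enforced by log-parameterization, and the 1–2 parameter problem is
   minimized by Nelder–Mead from two starts (median source variance, and
   a curvature start from regressing target variance on σ₁₂²).  The
   third parameter c — a dose-independent covariance offset — is off by
   default; inverse-bootstrap-variance weighting is available, with
   unweighted least squares the default.

## Statistical test

Both directed models are fitted to the same per-dose covariance
elements, and each model's per-dose error is the sum over the two
species of the squared variance mismatch.  Because the doses are shared
the comparison is paired: a Wilcoxon signed-rank test on
d_i = ε_i^reverse − ε_i^forward first tests the null of equal fit
quality (two-sided, gate α = 0.05, configurable); if rejected, the model
with consistently smaller errors is favored and the reported headline
p-value is the *one-sided* signed-rank p for that model.

For N ≤ 25 retained pairs the null distribution of the rank sum is
enumerated exactly via its generating function (ranks doubled so that
tie-averaged ranks stay integral); beyond 25 a normal approximation with
continuity correction and tie-corrected variance is used.  Zero
differences are dropped and counted; ties receive average ranks.  The
smallest attainable one-sided p at N pairs is 2⁻ᴺ (≈1.2×10⁻⁷ at N=23) —
a uniformly favorable comparison reports exactly this floor.  The
regulation call (activation vs repression) is the sign of the
bootstrap-precision-weighted aggregate σ̂₁₂ across doses.

## Validation studies and problem sizes

`induce.validation` (driven by `scripts/acceptance.py` and the
acceptance tests) runs: closed-form vs numeric covariance agreement over
1000 random parameter draws; exactness of the quadratic law on analytic
paths and 10%-level recovery of (α, β) from sampled ensembles;
direction-discrimination power over 200 directed datasets and
false-call rate over 1000 severed-edge null datasets (both at the
reference 23 × 10⁴ conditions); Euler–Maruyama vs Lyapunov covariance
agreement (2×10⁴ cells, dt = 0.005) and single-trajectory ergodic
consistency (4×10⁵ retained steps); and the sign rule over 50 activating
plus 50 repressive datasets.  The run sizes are chosen to put
Monte-Carlo error comfortably below the tolerances being asserted while
keeping the full battery at minutes on one CPU.

## Known limitations

* The fitted law assumes equal decay rates for the pair; unequal rates
  rescale the quadratic coefficient and bias α̂ accordingly (the
  direction comparison is typically unaffected, since both directions
  share the misspecification).
* Noise amplitudes Q are assumed dose-independent.  A ligand that
  directly modulates a species' intrinsic noise can mimic or mask
  directional signatures; this is not detected by the package.
* Feedback loops are outside the model class: motifs are acyclic, and a
  real feedback edge violates the constant-source-variance constraint in
  both directions.
* Absence of an open loop does not rule out unmeasured upstream nodes —
  many parameterizations of three-node motifs are indistinguishable from
  an isolated edge at the level of the measured covariance elements.
* The exact test treats doses as exchangeable paired observations;
  per-dose errors share fitted parameters, so they are not strictly
  independent.  The severed-edge calibration study measures the
  practical impact under the reference conditions.
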