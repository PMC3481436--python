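# Methods

## Model

The model tracks unactivated (x₁), M1 (x₂) and M2 (x₃) macrophages and the
cytokines IL-10 (x₄), TNF-α (x₅) and IL-1 (x₆) in the infarcted left
ventricle. Cells enter the unactivated pool at the exogenous monocyte
differentiation rate M(t) and all cell pools die at rate μ. Activation to
M1 is driven by IL-1 and TNF-α (Hill activation, inhibited by IL-10
through `g(c1; x4)`) and by contact with damaged myocytes
(`λ·Mc(t)·g(c; x4)·x1`); activation to M2 is driven by IL-10
(`k4·h(x4; c_il10)·x1`) plus phenotype switching M1→M2 at rate k1 and
M2 loss at k1′. Cytokines follow linear secretion–decay balances
(k5 x₃, k6 x₂, k7 x₂ against decays 2.5, 55, 10.5 per day). All states
are concentrations and are kept non-negative; the right-hand side raises
on negative or non-finite states rather than silently clipping trajectories.

Summing the three cell equations gives the conservation balance
dN/dt = M(t) − μN with N = x₁+x₂+x₃, which the code uses both for a priori
boundedness ceilings (`bounded_response`) and for the repaired global
stability argument below.

## Parameters

The kinetic rates are reconstructed from the twelve printed coefficients of
the saturated quadratic bound (see below). The diagonal entries give
μ+k2+k3+k4 = 1.6, μ+k1 = 0.275, μ+k1′ = 0.25 and the three decay rates;
the cross terms give k2+k3+k4 = 1.1+0.3 (split via the x₁x₂ vs x₁x₃
structure), k1 = 0.125−k1′ consistency, and k5/k6/k7 directly. This linear
system has the unique solution μ = 0.2, k1 = 0.075, k1′ = 0.05,
k2 = k3 = 0.55, k4 = 0.3. `params.bound_coefficients` recomputes the twelve
coefficients from the rate constants with exact rational arithmetic
(`fractions.Fraction`) so the round trip is bit-exact, and the
reconstructed fields are locked against modification by calibration
(`LOCKED_RATE_FIELDS`).

## Stability certification

With zero inputs the origin (healthy, macrophage-free tissue) is an
equilibrium. Using V(x) = ½‖x‖², saturating every Hill factor at 1 in
x·f(x) produces a quadratic form xᵀQx whose matrix has strictly negative
eigenvalues (−55, −10.5, −2.5, −1.81, −0.295, −0.0218), so the bilinear
comparison system is globally stable. The package audits two further steps
of the hand derivation and both fail as printed:

1. **Pointwise domination.** The claim that V̇(x) ≤ xᵀQx on the whole
   non-negative orthant is false, because the Hill factor is also saturated
   inside the *stabilizing* −kᵢ·h·x₁² loss terms, which makes them more
   negative in the bound than in the truth — the wrong direction for an
   upper bound. Counterexample: at x = (1,0,0,0,0,0) the true derivative is
   −μ = −0.2 while xᵀQx = −1.6. `pointwise_bound_dominates` finds
   violations at roughly half of random orthant states.
2. **Completed-square bookkeeping.** The printed sum-of-squares
   decomposition overdraws the x₃² budget: the standalone 0.05, the
   0.3·(x₁ coefficient 0.25)… terms add to 0.375 against the available
   0.25, a slack of −0.125 — far outside the 0.01 printed rounding. All
   other eleven monomials balance within 0.01.
   `sos_decomposition_check` reports the full slack table.

Neither defect threatens the conclusion. Global asymptotic stability of the
origin holds by a cascade argument: N = x₁+x₂+x₃ obeys dN/dt = −μN exactly
under zero input, so all cell pools decay to zero; the cytokines are
linear, exponentially stable systems driven by the decaying cell pools, so
they follow. The two failing acceptance tests document the broken
derivation steps rather than the (true) stability claim; they are left
failing intentionally.

## Equilibrium calibration

The chronic post-MI operating point is targeted at
(20, 1200, 3500, 0.73, 1.1, 5.9). Two structural facts shape the fit:

- **The unactivated target is infeasible.** With M1 = 1200 and M2 = 3500
  fixed, the M2 balance alone requires the unactivated pool to exceed
  ~2617 cells/ml (k4·x₁ ≥ μ+k1′ times 3500 minus k1·1200, with h ≤ 1), so
  x₁* = 20 cannot coexist with the other five components. The calibration
  therefore weights the x₁ residual at zero and pins the resulting flat
  direction with an analytic initializer that sets the M2-activation Hill
  factor to one half at the operating point, giving x₁* ≈ 5233.
- **An IL-10 residual floor exists.** Steady IL-10 is capped at
  k5·x₃/d_il10; with x₃ = 3500 that is 0.70 < 0.73, a provable relative
  residual of 0.075/1.825 ≈ 0.0411 no parameter choice can remove (k5 and
  d_il10 are locked). The calibration computes and reports this floor in
  its diagnostics instead of absorbing it.

The free parameters are the five Hill constants, λ and the baseline
monocyte rate, fitted in log₁₀ space with bounded trust-region least
squares and five multi-starts (fixed internal seed 42). λ and the myocyte
density enter only as the product λ·Mc, so the baseline myocyte density is
fixed at the post-MI plateau 3·10⁹ cells/ml and λ is fitted. The (c, λ)
direction is weakly identified at the operating point, so a weak log-space
ridge (weight 0.02, anchored at the analytic initializer) keeps the
optimizer at the analytic operating point rather than a bound corner; the
ridge changes the achieved M1/M2 residuals by less than the reporting
precision. Achieved steady state:
(5233.0, 1200.0, 3528.1, 0.706, 1.113, 5.826) — M1 within 10⁻⁵, M2 within
0.8%, IL-10 at its floor.

## Default infarction scenario

The monocyte input is baseline rate (1992.2 cells/ml/day from the
calibration) plus a gamma-density pulse, shape 3 / scale 1.75 days (peak
day 3.5, decayed to ~10⁻⁵ of peak by day 28), with peak total rate five
times baseline. Myocyte density declines as 6·10⁹·(0.5 + 0.5·e^(−0.5t)),
halving toward the plateau used in calibration. These shapes were committed
before any downstream result was inspected and were not tuned afterwards.
From the healthy initial state (2000, 0, 0, 0.1, 0.1, 0.1) the simulation
shows M1 accumulating faster over days 0–3 and a sustained M2 crossover at
day 5.52.

## Synthetic data and recovery

The generator integrates a ground-truth scenario and samples species at the
study design days (macrophage totals at days 1, 3, 5, 7, 14, 21, 28; IL-10
at 0.25, 3, 5; IL-1 at 0.25, 1, 3, 5, 7, 21; TNF-α at 0.25, 1, 3, 5, 7,
14, 21), applying mean-preserving lognormal noise (σ² = ln(1+cv²),
μ = −σ²/2) with five replicates per day and reporting the replicate mean
and its standard error. Phenotype-resolved M1/M2 counts are optional
(`include_phenotypes`). These sampling days and the default cv = 0.2 are
study conditions, fixed in advance.

Parameter recovery weights residuals by 1/se and fits selected rates in
log₁₀ space within ±2 decades. Two numerical choices matter: the
finite-difference step is set explicitly to 10⁻³ in log space, because the
optimizer's default step (~10⁻⁸) falls below the ODE integrator's noise
floor and yields useless Jacobians; and the forward model integrates at
rtol 10⁻⁷ for speed. Noiseless single-rate fits recover μ to ~10⁻⁷; with
cv = 0.2 noise the median relative error of the joint (μ, k1, k1′) fit
across 20 datasets stays below 30% (and is typically under 15%), with
k1′ — the smallest, least-observed rate — the noisiest.

Passing recovery tests show identifiability *under this design* only: they
say nothing about designs with fewer time points, other noise models, or
recovery of the Hill constants, which are close to non-identifiable from
these observables (the package flags wide posterior uncertainty when all
five are freed).

## Numerics

Integration uses LSODA with rtol 10⁻⁸ and a per-state absolute tolerance
vector (10⁻⁵ relative to typical cell scales, 10⁻¹⁰ for cytokines) — the
system is stiff, with cytokine decay at 55/day against cell dynamics at
0.2/day. Steady states come from a long settle integration followed by a
Powell-hybrid root polish. Crossover detection requires sustained
dominance (one day) and refines the crossing by linear interpolation.
Doubling the monocyte input scales the total-cell supremum by at most 2
(exact, from the conservation balance); individual pools can amplify
mildly beyond that through the IL-10 feedback (M2 observed at ~2.3×).

## Limitations

- The model is spatially homogeneous; infarct-zone gradients, neutrophils
  and fibroblasts are outside scope.
- The published chronic operating point is not exactly reachable: the
  unactivated-pool component is structurally inconsistent with the M1/M2
  targets, and IL-10 carries a 4.1% floor. Both are reported, not hidden.
- Hill constants are weakly identified from the default sampling design;
  fitted values should be read as an operating-point parameterization, not
  as measured affinities.
- The monocyte pulse amplitude and shape are plausible commitments, not
  fitted to infiltration data.
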