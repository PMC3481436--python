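# mimacro

A six-state ordinary-differential-equation model of macrophage polarization
in the left ventricle after myocardial infarction, with tools for
simulation, stability certification, equilibrium calibration, synthetic-data
generation and parameter recovery.

## Scientific background

After a myocardial infarction, monocytes infiltrate the damaged ventricle
and differentiate into unactivated macrophages. Damaged myocytes and
inflammatory cytokines drive these cells toward the classically activated
(M1, inflammatory) phenotype; the anti-inflammatory cytokine IL-10 drives
them toward the alternatively activated (M2, reparative) phenotype and
suppresses M1 conversion. The phenotypes in turn secrete the cytokines that
regulate them: M1 cells secrete TNF-α and IL-1, M2 cells secrete IL-10. A
healthy resolution of the inflammatory response shows M1 cells accumulating
fastest in the first days after infarction, with the M2 population
overtaking them within about ten days as the wound moves into its
reparative phase.

## The model

The state is

| symbol | meaning                       | units        |
|--------|-------------------------------|--------------|
| x₁     | unactivated macrophages       | cells/ml     |
| x₂     | M1 macrophages                | cells/ml     |
| x₃     | M2 macrophages                | cells/ml     |
| x₄     | IL-10                         | pg/ml        |
| x₅     | TNF-α                         | pg/ml        |
| x₆     | IL-1                          | pg/ml        |

driven by two exogenous inputs: `M(t)`, the monocyte differentiation rate
(cells/ml/day), and `Mc(t)`, the local myocyte density (cells/ml). The
dynamics are

```
dx1/dt = M(t) − μ x1 − [k2 h(x6;c_il1) + k3 h(x5;c_ta)] g(c1;x4) x1
         − k4 h(x4;c_il10) x1 − λ Mc(t) g(c;x4) x1
dx2/dt = [k2 h(x6) + k3 h(x5)] g(c1;x4) x1 + λ Mc(t) g(c;x4) x1
         − (μ + k1) x2
dx3/dt = k4 h(x4) x1 + k1 x2 − (μ + k1') x3
dx4/dt = k5 x3 − d_il10 x4                      (IL-10)
dx5/dt = k6 x2 − d_ta x5                        (TNF-α)
dx6/dt = k7 x2 − d_il1 x6                       (IL-1)
```

with Hill activation `h(x;c) = x/(x+c)` and inhibition
`g(c;x) = c/(c+x)`. The kinetic rates (μ = 0.2/day, k1 = 0.075,
k1' = 0.05, k2 = k3 = 0.55, k4 = 0.3, k5/k6/k7 = 5·10⁻⁴/7·10⁻⁴/6·10⁻⁴,
cytokine decays 2.5/55/10.5 per day) are fixed; the Hill constants, the
myocyte-driven activation rate λ and the baseline monocyte rate are
calibrated to the published chronic post-infarction operating point
(M1 = 1200, M2 = 3500 cells/ml). Saturating every Hill factor at one
yields a quadratic upper-bound form whose negative-definiteness certifies
stability of the healthy origin under zero inputs; the package builds that
bound, checks its eigenvalues, and also audits the hand completed-square
decomposition term by term (see `docs/methods.md` for two defects this
audit exposes).

## Worked example

```python
import mimacro as mm

p, u, s0 = mm.default_mi_scenario()       # calibrated params + MI inputs
traj = mm.integrate(s0, p, u, (0.0, 30.0))
print(mm.crossover_day(traj))             # 5.52  (M2 overtakes M1, day)

cal = mm.default_calibration()
print(cal.diagnostics["steady_state"])
# [5232.97, 1199.99, 3528.09, 0.706, 1.113, 5.826]
print(cal.diagnostics["il10_residual_floor"])   # 0.0411 (provable IL-10 gap)

cert = mm.quadratic_bound(p)
print(cert.verdict)                       # 'globally_stable'
```

Running `python examples/01_simulate_mi.py` prints:

```
peak m_un :    22844.6 cells/ml at day  5.50
peak m1   :     2940.4 cells/ml at day  7.25
peak m2   :    11126.3 cells/ml at day 11.00
M2 overtakes M1 (sustained) at day 5.52
```

which reproduces the expected post-MI pattern: M1 accumulates faster over
days 0–3, M2 dominates well before day 10, and the system settles toward
the calibrated chronic state. The other scripts in `examples/` each walk
one capability: stability certification (`02`), equilibrium calibration
(`03`), synthetic data + rate recovery (`04`, typical noisy errors of a
few percent to ~13%) and input estimation from a time course (`05`,
round-trip error 0.8% RMS).

## Command line

```
mimacro params show|validate|derive
mimacro inputs fit DATA.csv --mu 0.2 -o profiles.json
mimacro simulate [--params P.json] [--t-end 30] [-o traj.csv] [--plot fig.png]
mimacro stability certify [-o cert.json]
mimacro synth generate [--seed N] [--noise-cv 0.2] [-o data.csv]
mimacro calibrate e2 [-o result.json]
mimacro calibrate recover --free mu --free k1 [--seed N]
mimacro run [--out-dir DIR] [--with-synthetic]
```

## Tests and reproduction

```
python -m pytest -q tests/
```

The suite contains unit and property-based tests plus end-to-end
acceptance tests that recompute each headline quantity from scratch. Two
acceptance tests fail by design: they check two steps of the hand-derived
stability argument (pointwise domination by the saturated quadratic form,
and the completed-square bookkeeping) that are genuinely incorrect as
printed; `docs/methods.md` gives the counterexamples and the repaired
argument. Everything else passes.

To regenerate the headline numbers:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This recomputes the quadratic-bound coefficients, the zero-input
equilibrium, the calibrated post-MI steady state and the M1/M2 crossover
day, and writes them as JSON. The pipeline is deterministic; the seed only
controls the random starting guess of the zero-input equilibrium search.
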