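# roppol

Estimation of positive- and negative-feedback strengths from steady-state
ROP1 polarity profiles in pollen tubes.

Tip growth in pollen tubes is driven by a polarized cap of active ROP1 (a
plant Rho GTPase) on the apical plasma membrane. At steady state the
membrane concentration profile R(x) — x the arc-length coordinate with the
tip at x = 0 — balances three processes: self-activation through positive
feedback (rate k_pf, superlinear with exponent α > 1, damped by depletion
of the free cytosolic pool R_tot), deactivation through negative feedback
(rate k_nf, linear), and lateral diffusion (D₁):

    −D₁ R″ = −k_nf R + k_pf (1 − ∫R dx / R_tot) R^α,   R(±L₀) = 0.

Every positive solution of this integro-differential equation is a scaled,
compressed copy of one canonical bell shape: R(x) = λ U_α(μx), where U_α
solves the nondimensionalized problem −u″ = −u + u^α with zero boundary
values, μ = √(k_nf/D₁), and λ is a positive root of the scalar calibration
equation

    k_nf/k_pf − λ^{α−1} + λ^α √(D₁/k_nf) |U_α| / R_tot = 0,

which has zero, one, or two roots according to the sign of a discriminant.
This reduces fitting a nonlinear IDE to estimating the two shape
parameters (λ, μ) under the linear existence constraint
μ R_tot − λ|U_α| > 0, and converting back through k_nf = D₁μ²,
k_pf = D₁μ² / (λ^{α−1} − λ^α|U_α|/(μR_tot)).

The package provides:

- **`roppol.core`** — collocation solution of the reference problem,
  the existence discriminant, calibration-root finding, and all
  shape ↔ rate conversions;
- **`roppol.cnls`** — constrained nonlinear least squares for a single
  tube (reparametrized as ν = μ/λ so the constraint becomes a box bound),
  with normal-theory covariance of (μ̂, λ̂);
- **`roppol.cmm`** — constrained method of moments for a tube
  population: averages per-tube fits, removes the estimation-noise bias
  from the between-tube covariance, projects it to positive
  semidefiniteness, and propagates uncertainty into (k_nf, k_pf) by the
  delta method;
- **`roppol.simulate`** — generators for single tubes, populations with
  (μᵢ, λᵢ) from a truncated bivariate normal, and "raw" matrices with
  baseline, outliers and ~25% missingness;
- **`roppol.preprocess`** — iterative-PCA imputation/denoising and
  boundary normalization of raw matrices;
- **`roppol.cli` / `roppol.io`** — a `roppol` command-line tool and
  CSV/JSON formats.

## Worked example

```python
import numpy as np
from roppol import (ModelConstants, Rates, ShapeParams, SimulationDesign,
                    fit_single, simulate_single, solve_lambda, solve_reference)

consts = ModelConstants()            # alpha=1.2, D1=0.2, L0=15, Rtot=30
ref = solve_reference(alpha=consts.alpha, c=consts.l0)
print(f"peak U(0) = {ref.peak:.5f}, mass |U| = {ref.mass:.4f}")

report = solve_lambda(Rates(knf=0.2, kpf=0.3), consts, ref)
print(f"calibration roots: {report.roots[0]:.4f}, {report.roots[1]:.4f}")

design = SimulationDesign(step=0.1, sigma=0.2, seed=42)
tube = simulate_single(ShapeParams(lam=0.6, mu=1.0), design, ref,
                       rng=np.random.default_rng(42))
fit = fit_single(tube, consts, ref)
print(f"lam = {fit.shape.lam:.4f}, mu = {fit.shape.mu:.4f}, "
      f"knf = {fit.rates.knf:.4f}, kpf = {fit.rates.kpf:.4f}")
```

prints

```
peak U(0) = 1.61051, mass |U| = 13.0871
calibration roots: 0.2160, 0.5994
lam = 0.6007, mu = 1.0286, knf = 0.2116, kpf = 0.3144
```

The reference bell peaks at 1.61051 with integral 13.09; at the wild-type
rates (k_nf, k_pf) = (0.2, 0.3) the calibration equation has two roots and
the data-relevant larger one is λ ≈ 0.6 with μ = √(0.2/0.2) = 1, so the
profile peaks at λU(0) ≈ 0.966. A tube simulated at that truth with noise
SD 0.2 on a 301-point grid is fit back to within a few percent, and the
recovered rates sit near the generating (0.2, 0.3).

The same pipeline runs from the shell:

```sh
roppol simulate --mode population --m 50 --step 0.1 --seed 1 --out tubes.csv
roppol fit-pop --input tubes.csv --out pop.json
```

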