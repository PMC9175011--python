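# Methods

## Model

Active ROP1 on the pollen tube membrane is described at steady state by a
semilinear balance with a depletion term,

    −D₁ R″(x) = −k_nf R(x) + k_pf (1 − ∫R/R_tot) R(x)^α,  R(±L₀) = 0,

on the arc-length interval [−L₀, L₀] with the apical tip at x = 0. The
negative feedback is linear; the positive feedback is superlinear
(g(u) = u^α, α > 1) and saturates through the fraction of free cytosolic
ROP1, 1 − ∫R/R_tot. Working units follow the source constants: x in μm,
intensities on the normalized acquisition scale; D₁ is treated as a
working-unit constant. The defaults α = 1.2, D₁ = 0.2, L₀ = 15, R_tot = 30
are the empirically anchored wild-type values, and all four are held fixed
during estimation: α trades off against μ, and R_tot is not identifiable
from membrane data alone, so only (k_nf, k_pf) are estimated.

Every positive solution factors as R(x) = λ U_α(μx), with U_α the positive
solution of −u″ = −u + u^α, u(±c) = 0. The compression is μ = √(k_nf/D₁)
and λ solves

    f(λ) = k_nf/k_pf − λ^{α−1} + λ^α √(D₁/k_nf)|U_α|/R_tot = 0.

f decreases to a unique minimum at λ* = (α−1)/α · μR_tot/|U_α| — where
f(λ*) equals the existence discriminant Λ — and increases up to
λ_max = μR_tot/|U_α|, where the membrane mass λ|U_α|/μ would exhaust
R_tot and f = k_nf/k_pf > 0. Hence: Λ > 0 means no positive solution,
Λ = 0 one (tangency, declared when |Λ| ≤ 1e−9; exact tangency is
measure-zero), Λ < 0 two, bracketed on (0, λ*) and (λ*, λ_max) and found
by Brent's method (residual tolerance 1e−8 asserted). The inverse map is
k_nf = D₁μ², k_pf = D₁μ²/(λ^{α−1} − λ^α|U_α|/(μR_tot)), valid strictly
inside the constraint μR_tot − λ|U_α| > 0.

## Reference solution

U_α is computed once per (α, c) by `scipy.integrate.solve_bvp`
(collocation, tolerance 1e−10) on [−c, c] with c = 15 by default. The
problem also admits u ≡ 0; the solver is seeded with the closed-form
infinite-domain ground state u(x) = ((α+1)/2)^{1/(α−1)}
sech^{2/(α−1)}((α−1)x/2), which satisfies the same ODE on the line, so
it lands on the positive branch (a peak below 1e−6 is treated as failure).
The solution is stored on a uniform 2001-point grid; |U_α| is the
composite trapezoid over that grid, cross-checked against Simpson
(divergence above 1e−4 relative raises). Profiles R(x) = λU_α(μx) are
evaluated by a natural cubic spline on the stored grid, extended by zero
outside [−c, c]; this extension is what the Dirichlet construction on the
μ-scaled domain implies, and at c = 15, α = 1.2 the boundary tail is
~3e−4 so the single stored solution serves every μ ≥ 1 encountered (and
mildly smaller μ, whose support extends past the data window where the
profile is effectively zero). The solution can be exported/imported as a
plain-text table so fits are bit-reproducible against a fixed reference.

At c = 10 the infinite-domain tail at the boundary is ~1.3% of the peak,
so the finite-domain solution necessarily deviates from the closed form
by that order near ±c; tests bound the deviation by the tail there and
apply the strict 1e−3·peak criterion at c ≥ 15.

## Single-tube estimation (CNLS)

Observations y_j = λU_α(μx_j) + ε_j, ε_j i.i.d. mean 0, variance σ².
The existence constraint is linear in (μ, λ); substituting ν = μ/λ turns
it into the box ν > |U_α|/R_tot, λ > 0, solved with
`scipy.optimize.least_squares` (trust-region reflective, analytic
Jacobian, bounds offset by 1e−8 to keep the feasible set open). Starting
values come from the data: λ₀ = y(nearest x to 0)/U_α(0) (ties broken
toward smaller |x|, then smaller x) and μ₀ = λ₀|U_α| / Σ_{i≥2} y₍ᵢ₎δᵢ,
the left-Riemann estimate of the profile integral; a nonpositive Riemann
sum falls back to μ₀ = 1 with a warning. If the default start fails or
ends on the constraint boundary, up to 5 log-normally perturbed restarts
(seeded) are tried and the best residual kept — the two-root structure of
the calibration equation can make the RSS surface bimodal.

σ̂² = RSS/(n−2). Off the boundary, the covariance of (μ̂, λ̂) is
σ̂²K̂⁻¹/n with K̂ the sample mean of ∇R ∇Rᵀ at θ̂, gradients
(λx U_α′(μx), U_α(μx)) from the spline and its derivative; 95% CIs are
θ̂ ± 1.96·SE, assuming Gaussian errors (the stated moments plus the
normal-theory coverage construction). A fit whose ν̂ sits within 1e−6 of
the bound is flagged `on_boundary` and its covariance withheld: the
constraint-saturated asymptotics are deliberately out of scope (the case
does not arise in real tubes).

All 2-vectors and 2×2 matrices are ordered (μ, λ).

## Population estimation (CMM)

Tubes i = 1..m carry θᵢ = (μᵢ, λᵢ) drawn from a distribution on the
feasible set with mean θ₀ and covariance Σ₀; only these two moments are
assumed. The estimator: per-tube CNLS fits (unfittable tubes are dropped
with a warning and counted, never silently); θ̂₀ = unweighted mean of the
θ̂ᵢ (fidelity to the published estimator even under unequal nᵢ);
σ̂² = ΣRSSᵢ/Σ(nᵢ−2); Σ̂₀ = sample covariance (divisor m−1) minus the
estimation-noise bias σ̂²·meanᵢ(JᵢᵀJᵢ)⁻¹, with Jᵢ the nᵢ×2 profile
Jacobian at θ̂ᵢ; a non-PSD result is projected by clipping negative
eigenvalues to zero (idempotent on PSD input; raw eigenvalues are
reported). Rates follow from θ̂₀; the asymptotic covariance of θ̂₀ is the
simple-mean CLT (sample covariance of the θ̂ᵢ divided by m), which is
accurate whenever per-tube estimation error is small against the
population spread — the regime of all designs here — and is labeled as
such in the JSON output. Delta-method CIs for (k_nf⁰, k_pf⁰) use a
central-difference Jacobian of the rate map (step 1e−6 × scale); the
population-level rate correlation propagates Σ̂₀ through the same
Jacobian.

## Synthetic data

The generators reproduce the study conditions. Single tubes: uniform
grids on [−15, 15] with steps 0.6/0.3/0.1 (n = 51/101/301), Gaussian
noise with σ = 0.2 by default (0.4 as the high-noise variant), truth
(λ, μ) = (0.6, 1.0) — equivalently (k_nf, k_pf) = (0.2, 0.3).
Populations: (μᵢ, λᵢ) from the bivariate normal with SDs 0.06, 0.06 and
correlation 0.8, truncated to the feasible set by rejection (the design
mean sits ≫ 3 SD from the boundary, so truncation is negligible; an
acceptance rate below 1% aborts); case designs m = 10/10/50 paired with
n = 51/101/301. Raw matrices: 12 tubes on the centered 173-point grid at
0.1205 μm spacing, a shared positive baseline of 0.2 × the population
peak intensity and 1% outliers at ±5σ (both invented fixtures emulating
uncalibrated background and acquisition glitches), and 25%
missing-at-random entries. Gaussian noise is the default error law
throughout — the inference relies on asymptotic normality — with the
generator seeded end-to-end for bit-reproducibility.

What the generators do not emulate: spatially correlated noise,
per-tube gain differences, irregular (non-grid) sampling, and asymmetric
profiles. Passing tests therefore demonstrate correctness of the
estimators under the stated observation model, not robustness to every
artifact of real acquisitions.

## Preprocessing

Iterative-PCA imputation: missing cells start at column means; the loop
{column-center, rank-k truncated SVD reconstruction, refill only missing
cells} runs until the Frobenius-relative change on imputed cells drops
below 1e−6 or 500 iterations (configurable; non-convergence returns the
last iterate with a warning — convergence is linear and noisy matrices
may need a few thousand iterations at tight tolerances). Observed cells
are untouched during the loop; the final step replaces all cells by the
rank-k reconstruction (denoising), and the retained-variance fraction is
reported. Column centering is used because row centering would destroy
the bell shape. Boundary normalization: y = (ỹ − ȳ_B)/ȳ_B with ȳ_B the
pooled mean over cells with |x| > 8 (per-tube normalization available as
an option); the normalized boundary-region mean is zero by construction,
and negative excursions are kept, as the observation model permits.

Normalization divides intensities by R₀ = ȳ_B, which shifts the rates by
(k_nf, k_pf) → (k_nf, k_pf R₀^{α−1}); equivalently, fits on the
normalized scale should use R_tot/R₀. Because the bell tail is not
exactly zero beyond |x| = 8, ȳ_B slightly exceeds the true baseline,
which is the main source of the (small, ~0.01–0.02 on μ₀ and λ₀)
end-to-end degradation of the raw pipeline relative to clean data; the
acceptance test asserts degradation bounds of 0.2 (μ₀) and 0.1 (λ₀)
chosen a priori from this mechanism.

## Problem sizes and numerical choices

Monte-Carlo acceptance checks run 200 replicates (single-tube n = 301,
σ = 0.2; population m = 50, n = 301), a scale at which Monte-Carlo
standard errors are small enough to resolve sub-1% bias while the whole
suite stays interactive (~30 s). Bias is compared to truth at 3 MC
standard errors, covariance-entry means at 2, and CI coverage against
[0.90, 0.99] around the nominal 95%. Root-finding uses machine-precision
Brent brackets; the optimizer runs at xtol = ftol = gtol = 1e−12.

## Limitations

- The boundary (constraint-saturated) case is detected and flagged, not
  estimated; its nonstandard asymptotics are out of scope.
- The exact refined asymptotic covariance of θ̂₀ is replaced by the
  simple-mean CLT, adequate when nᵢ is large relative to the population
  spread but anti-conservative for very noisy, very short tubes.
- α is fixed, not estimated; misspecified α biases μ̂ (they are nearly
  confounded).
- The number of PCA axes is a user choice (9 by default); no
  cross-validation is performed.
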