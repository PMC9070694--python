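# Methods

## Sampling engine

The target density is always expressed through a potential
U(z) = −log L(x(z)) − log|∂x/∂z| on an unconstrained sampling scale z;
per-parameter transforms are identity (sign-free parameters), log
(positive parameters) and logit (interval-bounded parameters), each
with its Jacobian folded into U so that the transformed density is the
correct push-forward.  The Gaussian residual likelihood treats the
observation error σ² as one more unknown, sampled on the log scale; for
SAXS and reflectivity the residuals are formed on the natural logarithm
of the intensity (any other base would only rescale σ²).

**Leapfrog.**  Half-kick / drift / half-kick with step ε and mass
matrix M (momentum covariance).  The integrator is exactly
time-reversible and volume-preserving; tests verify position recovery
to 1e-10 after a momentum flip and the second-order scaling of the
energy error (|ΔH| drops ~4× when ε halves).  The normalization
constant of the momentum Gaussian is dropped everywhere — it cancels in
the Metropolis ratio for a fixed mass matrix.

**Kernels.**
- *HMC*: fixed L leapfrog steps, Metropolis correction
  min{1, e^{−ΔH}}.  Trajectories whose energy is non-finite or whose
  |ΔH| exceeds 1000 are rejected and counted as divergent; the run
  continues (an all-divergent burn-in aborts with a diagnostic).
- *NUTS*: the slice-sampling binary-tree variant, default max depth 10.
  The doubling stops at the U-turn criterion evaluated with M⁻¹p
  velocities, on divergence, or at the depth cap; the draw is uniform
  over the slice-admissible candidate set, and the dual-averaging
  statistic is the tree-averaged Metropolis probability.  Which tree
  variant the original analyses used is not documented; the slice form
  is the conservative choice and satisfies detailed balance.
- *Random-walk Metropolis baseline*: isotropic-by-coordinate normal
  proposal; a helper derives the proposal s.d. from reference draws as
  sqrt(var) × 2.4/√N (classical optimal scaling), mirroring the
  baseline comparisons.

**Step-size adaptation.**  Nesterov dual averaging with the standard
constants (γ = 0.05, t₀ = 10, κ = 0.75, µ = log 10ε₀), target
acceptance 0.8, active only during burn-in; after burn-in ε freezes at
the averaged value.

**Mass matrix.**  Three strategies: identity;
`inverse_variance_diag` = diag(1/var) of warm-up draws (the inverse
diagonal covariance preconditioner); `gradient_scaled_diag` = mean
|∂U/∂z_i| over probe points snapped to a few magnitude levels (the
coarse two-level preconditioning used for the holography problem, e.g.
{400, 1}).  `run_chain` can estimate the mass mid-burn-in; the
high-level pipeline instead runs an explicit pre-run and restarts.  The
pre-run itself is whitened by a diagonal curvature mass — second
differences of U at the start point — because the raw parameter scales
of the scattering posteriors span four decades and an identity-mass
NUTS warm-up would waste its budget growing maximal trees.  This
curvature initialization is the package's own design choice; the
strategy interface still exposes exactly the two published
preconditioners for the production phase.

**Constraints.**  `reflect_at_constraint` mirrors the momentum about a
constraint surface (Householder reflection), preserving kinetic energy
exactly under an identity/whitened metric.  With a non-identity mass
matrix an exact energy-preserving bounce would need the M⁻¹ inner
product; the op is intended for use on the whitened sampling scale.

**Determinism.**  One seeded generator owned by each run; identical
seeds give bit-identical chains.

## Forward models

**SAXS (polydisperse spheres).**  The size integral is 61-node
Gauss–Legendre over R ± 5σ_R truncated at R > 0 with renormalized
normal weights; the resolution integral is a 21-node Gaussian kernel
over ±4σ_q.  The size-averaged curve is evaluated on a dense linear q
grid whose spacing resolves the fastest qR oscillation (Δq·R_max ≤ 1/6
rad) and cubic-spline interpolated onto the smearing nodes; against a
10×-density double Riemann sum the result agrees to ~2×10⁻⁵ relative.
The resolution width is sampled unconstrained and enters as |σ_q| (the
intensity is even in σ_q): its posterior can straddle zero, which is
exactly what the data show when the resolution is below the
information content of the curve.  Analytic parameter derivatives
(including quadrature-node motion with R and σ_R) make a gradient cost
about twice a forward evaluation.

**Reflectivity (effective-density model).**  Box parameters (thickness
h, dispersion δ, roughness σ per interface) induce a continuous
profile δ(z) = Σ δ_j w_j(z) with erf-smeared, telescoping weights that
sum to one at every depth, so material from thin layers penetrates its
neighbours — the regime where Névot–Croce damping fails (tests show
2%-level agreement with the damped box model at h = 100 Å, σ = 2 Å and
>5% divergence at h ≈ σ).  The profile is sliced into dz = 0.5 Å slabs
on a fixed dz lattice (window: 4×max σ beyond the outer interfaces,
boundaries snapped to the lattice so that window growth only adds
optically inert padding) and solved by exact Parratt recursion;
absorption is off by default (δ-only parameterization) with a β hook.
The staircase discretization is second-order: at dz = 0.5 Å the curve
carries ~(q·dz)²/12 relative error at the highest q; generator and fit
share the discretization, so recovery is unbiased, and the
self-convergence test (halving dz changes the curve < 1e-3) runs at
dz = 0.1 Å where the criterion is meaningful.  Gradients are computed
by adjoint differentiation of the recursion (it is holomorphic in the
slab dispersions) chained through the analytic erf-profile
derivatives; one gradient costs ~3 forward solves instead of 2N.

**XWFH (waveguide fluorescence holography).**  The gold number density
is φ_au(z) = N_au Σ a_k B̂_k(z) with clamped cubic B-splines on uniform
knots over the film, basis functions normalized to unit integral and
N_au = d_au × bulk gold density (so the profile is linear in both the
coefficients and the nominal thickness).  Standing-wave fields at the
incident energy/angle and at each emission energy/exit angle come from
the transfer solution of the stratified wave equation (amplitude
continuity at every slab interface; flux conservation verified for
non-absorbing stacks).  The hologram is the reciprocity form

I(α_f) = I₀[(1−f_el) Σ_l w_l ∫|E_in(z)|²|E_l(z;α_f)|² φ_au(z) dz + f_el B(α_f)],

with B the same integral over the total electron density.  The
original fluorescence/elastic intensity expressions are display
equations not recoverable from the available text; this reciprocity
reconstruction is flagged as such and is the standard approximation
for exit-angle-resolved fluorescence.  Line energies are the Lα₁,₂ and
Lβ₂,₁₅ group centroids with fixed relative weights 0.77/0.23
(tabulated emission rates, overridable).  Optical constants derive
from electron densities via the λ² Thomson scaling without anomalous
corrections, and the pixel→exit-angle map is linear with configurable
pitch — both adequate for the synthetic studies this model drives, and
both would need refinement for real beamline data.  Field solutions
are cached per geometry sub-vector, so finite-difference batches and
fixed-geometry samplers pay for the dynamical solve once.

## Diagnostics

ACF uses the biased (divide-by-n) estimator, FFT-accelerated and
verified against the direct sum to 1e-10, with ±1.96/√n significance
bounds.  ESS = n/(1 + 2Σρ_k) with Geyer initial-positive-sequence
truncation on lag pairs; cross-checked against arviz.  Summary tables
report moments on the physical scale after back-transforming draws;
t = mean/s.d. and the p-value is the empirical two-sided tail fraction
relative to zero with a 2Φ(−|t|) floor when no draw crosses zero
(degenerate zero-variance parameters are flagged).  Correlation
matrices accept derived columns (e.g. a total-thickness expression).
Credible bands are pointwise 2.5/50/97.5 percentiles of the forward
model over post-burn-in draws.

## Synthetic data

Generators carry the published posterior means as ground truth and the
corresponding instrument grids: SAXS — 100 log-spaced q in
[0.002, 0.05] Å⁻¹; reflectivity — 200 linear q in [0.02, 0.60] Å⁻¹ at
λ = 0.6199 Å (20 keV); XWFH — a pixel axis over the waveguide exit-cone
region at 12.1 keV incidence, gold monolayer as a single nonzero spline
coefficient at the buried PS/PtBA interface.  Noise is multiplicative
log-normal, y = f·exp(ε), ε ~ N(0, σ²), matching the Gaussian
log-intensity residual model; σ² values are the published residual
variances.  The truth record travels with each dataset.

What the generators do **not** emulate: counting statistics
(intensity-dependent errors), instrumental backgrounds beyond a flat
term, beam damage or drift, detector nonlinearity, and — for XWFH —
real anomalous dispersion near the Au L edges.  Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
stated noise model, not robustness to real-beamline systematics.

## Problem sizes and numerical choices

Recovery studies run at the published chain lengths where stated (SAXS:
500 warm-up + 1500 NUTS draws after a 100-iteration pre-run); the
reflectivity fit uses 100 + 300 + 600 iterations of L = 10 HMC, and the
model-selection study 80 + 150 + 400 per fit — sizes chosen so the
posterior moments are stable at the precision the assertions need.  The
scaled holography studies freeze the geometry (spline-only sampling) or
check the thickness-degeneracy claim through the posterior curvature
(Laplace approximation): the full 38-parameter holography fit is a
production workload, and its soft total-thickness ridge would need far
longer chains than a test suite should run.  Finite-difference
gradients (used where no analytic Jacobian exists) are central
differences with per-coordinate step max(1e-5, 1e-5|z_i|), evaluated
through one batched model call; forward-model implementations flag
absurd parameter excursions (non-finite values, quadrature or slicing
grids beyond 1e5 points, underflowed quadrature weights) as invalid
rather than allocating unbounded work, which the samplers treat as
divergent proposals.

## Known limitations

- No absorption in the reflectivity fit parameterization (hook only).
- The XWFH intensity is a simplified reciprocity reconstruction (see
  above); fluorescence yields, self-absorption and detector solid-angle
  factors are absorbed into I₀ and the line weights.
- Burn-in is user-specified; there is no automatic convergence test
  (trace inspection is the intended workflow, as in the original
  analyses).
- The constraint-reflection op assumes a Euclidean metric.
- Full (non-diagonal) mass matrices are supported in the data type but
  the adaptation strategies estimate diagonals only.
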