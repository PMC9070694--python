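# hmcscatter

Hamiltonian Monte Carlo parameter estimation for X-ray scattering
analysis.

X-ray scattering data analysis is an inverse problem: a physical model
with parameters **x** = {x₁…x_N} predicts a measured 1-D curve, and the
parameters and their uncertainties must be recovered from noisy data.
Classical random-walk MCMC explores the posterior p(**x**) slowly —
effective sample sizes of a few percent are typical.  `hmcscatter`
implements gradient-based Hamiltonian Monte Carlo for this setting: an
auxiliary momentum **p** ~ N(0, **M**) is introduced, the Hamiltonian

    H(x, p) = U(x) + ½ pᵀ M⁻¹ p,      U(x) = −log p(x)

is integrated with the time-reversible leapfrog scheme (step ε, L
steps), and each trajectory endpoint is accepted with probability
min{1, exp(H_old − H_new)}.  The No-U-Turn sampler (NUTS) automates the
trajectory length; dual averaging adapts ε toward a target acceptance;
diagonal mass-matrix preconditioning (inverse posterior variance, or
coarse gradient-magnitude scaling) whitens badly scaled problems.

The likelihood is a Gaussian residual model on the (usually logarithmic)
intensity with a single unknown variance σ² sampled alongside the
physical parameters.  Three forward models are included, each with exact
analytic parameter gradients so that HMC runs at forward-model cost:

- **SAXS of dilute polydisperse spheres** — sphere form factor
  F(q,R) = 3V(R)[sin qR − qR cos qR]/(qR)³, normal size distribution
  (mean R, width σ_R), Gaussian q-resolution smearing (σ_q), volume
  normalization, scale I₀ and flat background I_b.
- **Specular reflectivity of a smeared multilayer** (supported lipid
  bilayer in water on Si) — the effective-density model builds a
  continuous dispersion profile δ(z) from error-function-smeared
  interfaces, valid when roughness is comparable to layer thickness, and
  computes |r(q)|² by exact Parratt recursion on thin slabs (adjoint
  differentiation supplies ∂R/∂(thickness, dispersion, roughness)).
- **X-ray waveguide fluorescence holography (XWFH)** — a buried gold
  monolayer in a PS/PtBA polymer waveguide on Pd/Cr/Si; the gold depth
  profile is a cubic-B-spline expansion and the exit-angle-resolved
  hologram is the reciprocity product of incident and exit standing-wave
  fields.

Chain diagnostics mirror standard MCMC practice: autocorrelation
functions with 95% zero-correlation bounds, effective sample size (ESS)
with Geyer truncation, summary tables (mean, s.d., t-statistic,
empirical two-sided p-value), parameter correlation matrices with
derived columns, and pointwise 95% credible bands for model predictions.

## Worked example

Recover the sphere parameters from a synthetic SAXS curve generated at
the published study conditions (R = 757.7 Å silica spheres, 100
log-spaced q points in [0.002, 0.05] Å⁻¹, log-normal noise):

```python
from hmcscatter.pipeline import fit_synthetic
from hmcscatter.synthetic import saxs_table1

res, truth = fit_synthetic(saxs_table1(seed=3), kernel="nuts",
                           n_prerun=100, n_warmup=200, n_draws=300, seed=3)
print(res.summary()[["mean", "sd", "t_stat", "p_value"]])
```

Output from this exact invocation:

```
               mean            sd      t_stat       p_value
I0         1.327978  8.613142e-03  154.180392  0.000000e+00
Ib         0.000020  2.895219e-07   69.129504  0.000000e+00
R        757.313171  1.124109e+00  673.700847  0.000000e+00
sigma_R   59.106108  8.802509e-01   67.146890  0.000000e+00
sigma_q    0.000006  8.897975e-05    0.068987  9.666667e-01
sigma2     0.002108  3.525264e-04    5.980574  2.223532e-09
```

Every generating parameter is recovered within about one posterior
standard deviation (truth: I₀ = 1.34, I_b = 2.00×10⁻⁵, R = 757.7 Å,
σ_R = 59.5 Å).  The resolution width σ_q is the one exception by
design: its posterior straddles zero (t ≈ 0.07, p ≈ 0.97), meaning the
data cannot resolve the instrumental smearing — the model-assessment
conclusion that σ_q can be dropped from the model.

A command-line interface wraps the same pipeline:

```bash
hmcscatter simulate saxs_table1 -o curve.dat --seed 5
hmcscatter fit config.yaml          # chain + summary table + diagnostics
hmcscatter diagnose out/chain.npz   # ESS / ACF / correlation report
hmcscatter compare saxs_table1     # HMC vs random-walk ESS comparison
```

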