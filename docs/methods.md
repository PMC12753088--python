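# Methods

## Model and assumptions

All estimators consume per-SNP summary associations (γ̂_j, σ_Xj) with an
exposure and (Γ̂_j, σ_Yj) with an outcome, assumed to come from
non-overlapping samples of one population, with independent SNPs (linkage
equilibrium) and pre-harmonized alleles. The generating model is
Γ_j = βγ_j + α_j, where α_j is a direct (pleiotropic) SNP→outcome effect.
The estimators differ only in what they assume about the α_j:

| estimator | identifying assumption | recoding-invariant |
|---|---|---|
| IVW | E(α_j) = 0, α ⟂ γ (balanced + InSIDE) | yes |
| MR-Egger | α ⟂ γ under the fitted coding | no |
| MR-GRIP | α_jγ_j ⟂ γ_j² (VICE) | yes |
| weighted median | median(α_j) = 0 | yes |
| mode-based | mode(α_j) = 0 | yes |

MR-GRIP fits E(Γ̂_jγ̂_j | γ̂_j²) = α₀ + βγ̂_j² by WLS with weights
γ̂_j⁻²σ_Yj⁻² (the inverse variance of Γ̂_jγ̂_j with γ̂_j treated as
fixed). Both response and regressor are even in the per-SNP allele coding,
which is the whole point: the fit cannot depend on which allele is called
the effect allele. With the intercept constrained to zero the slope
collapses algebraically to the IVW estimate, so MR-GRIP is the
coding-invariant analogue of the IVW→MR-Egger generalisation. The
intercept α₀ = E(α_jγ̂_j) is the average direct contribution to the
genetic covariance of exposure and outcome; testing α₀ = 0 is the
directional-pleiotropy diagnostic. Under VICE, a nonzero α₀ implies
E(α|γ) ∝ 1/γ — pleiotropy that shrinks as instrument strength grows, as
expected when strong instruments are more biologically specific to the
exposure.

## Standard errors and reference distributions

All regression estimators report WLS coefficient standard errors with
multiplicative overdispersion whose residual scale is floored at 1:
`se = unit_se · max(1, σ̂)` where σ̂² is the weighted residual mean
square. This is the common summary-MR convention (fixed-effect SEs when
underdispersed, multiplicative random-effects SEs when overdispersed).
`residual_scale` reports the unfloored σ̂, so an exact fit shows ≈ 0.
P-values and CIs use the standard normal for IVW and a t distribution with
m−2 degrees of freedom for the MR-Egger and MR-GRIP slope and intercept;
the simulation engine's intercept *power* calculations use the normal
reference throughout, since that is the convention for the power tables
this engine mirrors. On calibration: in the balanced-pleiotropy scenario
the mean analytic SE tracks the empirical SD of the point estimates within
a few percent for all four regression estimators (asserted in the
acceptance suite).

The weak-instrument-adjusted MR-GRIP has no closed-form SE here; it
reports a leave-one-out jackknife, which the acceptance suite validates
against the empirical SD under balanced pleiotropy. The weighted median
and mode use a parametric bootstrap (γ̂*, Γ̂* redrawn from their sampling
distributions, default 1000 draws, explicit seed). Both estimators first
standardize the dataset to all-positive coding — a no-op for their point
estimates, which depend only on the ratios — so that the bootstrap draws,
and hence the reported SEs, are bit-identical under any input recoding of
the same data with the same seed.

## Weak-instrument adjustment

When σ_X is not negligible, γ̂² overestimates γ² and all the regression
estimators attenuate toward the null (regression dilution). The adjusted
estimator rewrites the NOME-limit MR-GRIP slope in moments of γ and
substitutes unbiased plug-ins under γ̂ ~ N(γ, σ_X²):

    γ̂(γ̂² − 3σ_X²)  →  γ³ (in the product with Γ̂)
    γ̂² − σ_X²       →  γ²
    γ̂⁴ − 6γ̂²σ_X² + 3σ_X⁴  →  γ⁴

with *fixed* weights w_j = σ_Yj⁻² (the γ̂-dependent inverse-variance
weights would reintroduce bias). Odd powers of γ̂ only ever appear
multiplied by Γ̂, so the adjustment retains recoding invariance. Under
very weak instruments the corrected denominator can reach zero or flip
sign; the implementation raises a numerical-instability error (also if any
leave-one-out denominator degenerates) rather than returning an unusable
number, and the simulation engine counts and excludes such replicates.

## Simulation engine

The four scenarios share a base of true effects γ_j and standard errors
(σ_Xj, σ_Yj); each replicate marks ⌈p_invalid·m⌉ SNPs invalid (uniformly
without replacement, re-drawn every replicate together with the α draws,
the random-effects reading of the assumptions), builds Γ_j, and samples
γ̂_j ~ N(γ_j, (weak_factor·σ_Xj)²), Γ̂_j ~ N(Γ_j, σ_Yj²). Defaults:
β = 0.2, α₀ = 0.02, pleiotropy scale 0.1, weak_factor 1 (5 in the weak
design). Choices the scenario definitions left open, resolved here:

- The directional terms (the constant α₀ in scenarios 2–3, the
  (α_jγ_j + α₀²)/γ_j term in scenario 4) apply to invalid SNPs only;
  valid SNPs have Γ_j = βγ_j exactly. This is the only reading under
  which the IVW bias scales with p_invalid, as it must.
- Scenarios 2 and 4 orient the true γ all-positive before building Γ (so
  "directional" means directional under all-positive coding, and the
  scenario-4 product pool {γ_aγ_b} has positive mean); scenarios 1 and 3
  keep the orientation carried by the base. The estimators always see
  whatever orientation the sampled γ̂ carry; MR-Egger re-orients
  all-positive internally, which is exactly why it is biased in
  scenario 3.
- Non-integer p·m rounds up.
- One RNG stream per replicate is spawned deterministically from the study
  seed, so every method sees identical data within a replicate and the
  whole study is bit-reproducible.

In the study aggregates the weighted median and mode contribute point
estimates only (no bootstrap inside replicates); means, empirical SDs,
mean analytic SEs, normal-reference intercept power at P ≤ 0.05 and the
Spearman correlation of the two intercept p-value streams are reported.

### Synthetic base generator

`synthetic_base_effects` emulates a strong-instrument panel for a
quantitative exposure with a log-odds outcome: per-SNP F log-uniform on
[30, 1000] (arithmetic mean ≈ 280, the order of magnitude of a
well-powered urate- or lipid-style instrument set), σ_X uniform on
[0.003, 0.008], σ_Y uniform on [0.01, 0.04], random allele orientation.
What it does **not** emulate: linkage disequilibrium between instruments,
winner's-curse selection of instruments, allele-frequency structure,
binary-outcome liability scale, sample overlap, or the specific joint
spread of any real consortium table. Consequently, tests passing on this
base demonstrate the estimators' structural properties (invariance,
unbiasedness patterns, SE calibration) under the stated sampling model,
not agreement with any particular published analysis; quantities that
depend on the real tables' spread — e.g. intercept-test power at a given
α₀ — differ from published values in level while matching in pattern.

## Numerical choices

- Weighted designs are rejected (diagnostic error) when the column-scaled
  condition number exceeds 1e8 — e.g. MR-Egger with (near-)constant γ̂, or
  MR-GRIP when all γ̂² coincide and the regressor is constant.
- γ̂_j = 0 exactly: all-positive coding keeps sign +1 with a warning;
  ratio-based operations refuse such SNPs by name, and
  `exclude_zero_exposure` drops them with a log entry.
- The mode estimator uses a normal kernel with the modified-Silverman
  bandwidth 0.9·min(sd, mad)·m^(−1/5) scaled by φ (default 1), a
  1024-point grid over the ratio range ± 3 bandwidths, and parabolic
  refinement of the argmax. The weighted median interpolates the ordered
  ratios against centred cumulative weights, clamping outside the first
  and last midpoints.
- Multivariable MR-GRIP weights by γ̂_r⁻²σ_Y⁻² (reference exposure r), by
  the same fixed-γ̂ variance argument as the univariate case; per-reference
  results are reported separately rather than pooled, since each reference
  estimates under its own VICE-type assumption.
- The collider-correction and index-effect variants reuse the MR-GRIP
  regression core verbatim with the conditional coefficient vector in the
  response slot, weights γ̂⁻² × (response SE)⁻², and a free intercept by
  default (a zero-intercept option is exposed).
- Scatter-plot support: the genuine MR-GRIP mean curve is
  E(Γ̂|γ̂) = α₀/γ̂ + βγ̂ (odd in γ̂, undefined at 0); for visual
  comparison with IVW/Egger lines, a straight display line fixes the slope
  at the causal estimate and refits the intercept as the σ_Y⁻²-weighted
  mean of the residuals Γ̂ − β̂γ̂.

## Problem sizes

The packaged studies use m = 31 SNPs with 600 replicates per scenario
configuration (400 for the weak-instrument design) and 200 random codings
in the invariance sweep — sizes at which the Monte-Carlo error of a mean
estimate is ≈ 0.002 and every pattern of interest is resolved with wide
margin. Larger runs are a single `ScenarioConfig` away.

## Known limitations

- MR-GRIP shows a small positive finite-sample bias (order 0.002 at these
  problem sizes) under scenario-4-style inverse-strength pleiotropy; its
  mean is therefore checked at the 0.01 simulation tolerance rather than
  a pure Monte-Carlo band.
- The weak-instrument adjustment is not proven unbiased; with mean F near
  10 it removes most of the attenuation but can be unstable (degenerate
  denominators are raised as errors, and excluded replicates are counted).
- Correlated instruments, likelihood-based weak-instrument methods, radial
  variants, outlier removal and Steiger filtering are out of scope; inputs
  are assumed harmonized (no palindromic-allele or genome-build handling).
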