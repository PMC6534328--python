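# Methods

## Stimuli

A trial presents N = 70 samples drawn from a "beta mix": m equal-width,
end-joined beta components on contiguous unit intervals [0,1], [1,2], …, with
a sample placed as `component_index + Beta(α, β)`. The shape pair (α, β) is
(3.1, 1.1), (2.9, 2.9) or (1.1, 3.1) — negatively skewed, symmetric, positively
skewed components of near-equal variance (component SD ≈ 0.19 of the component
width; the three variances agree within ~1%). Component weights are
permutations of (0.2, 0.3, 0.5) for 3-beta or (0.1, 0.2, 0.3, 0.4) for 4-beta
mixtures. *Local* skewness refers to the component shape, *global* skewness to
the whole mixture (driven by the weight order).

Designs: E1 = 3 shapes × 6 weight permutations × 9 repeats = 162 trials
(3-beta); E2 = 3 × 24 × 2 = 144 trials (4-beta); E3 interleaves 72 trials of
each kind in 12 alternating mini-blocks of 10–14 trials; S1 replays the E1
design on an orientation range. Samples are linearly rescaled so the sample SD
equals exactly 7.27 / 7.20 / 7.55 cm (E1/E2/E3), then shifted by a jitter drawn
uniformly from the interval of shifts that keeps the sample mean within
±3.8 cm and every sample within ±20 cm; if that interval is empty the samples
are redrawn. Rescale-and-shift is affine, so sample skewness is untouched.

**Per-component counts.** By default each component receives exactly
`N × weight` samples (always an integer for these designs: 14/21/35 and
7/14/21/28), with positions i.i.d. within components. We read the choice
N = 70 as deliberate: sharp cluster-size peaks at exactly those counts are
impossible under binomial (fully i.i.d.) component membership, which smears
counts by ±3. `stratified=False` restores fully i.i.d. draws; the empirical
weight-convergence property holds under both.

**S1 orientations** are treated as linear values on [0°, 180°) — no circular
wrap, since the design keeps all stimuli inside a 180° range. The E1 geometry
is mapped by the screen-to-angle factor 4.5 (target SD 32.7°, mean range
90° ± 17.1°). These S1 conventions are package choices; only the sub-180°
constraint is inherited from the design.

**True statistics** per trial: arithmetic mean; population skewness
m₃/m₂^1.5 (the estimator is a package choice); mode = argmax on a 4096-point
grid over the position range of a diffusion kernel density estimate whose
bandwidth is selected by the plug-in fixed-point rule (smoothing well suited
to multimodal data). The wide, fixed grid keeps the fixed-point root-finding
stable; bandwidth selection was checked against the asymptotic rate for
normal samples (selected 0.194 vs theoretical 0.194 at n = 5000, σ = 1).

## Clusters-of-Samples representation

Join probabilities `P(j→l) ∝ exp(−d_jl²/γ)` (l ≠ j) are computed with a
max-subtracted exponent for stability; γ carries cm² so the exponent is
dimensionless. The stay-alone option is removed exactly (the limit the model
motivates for large N), so every cluster has ≥ 2 members. Duplicate positions
are allowed and join each other with maximal probability. A representation is
summarised by centroids `c_k` (member means) and weights `w_k = n_k/N`, which
makes `Σ_k c_k w_k` equal the sample mean to machine precision — clustering
alone cannot bias Mean reports.

Ensembles of R = 1000 runs per (trial, γ) are the default; R = 200 with a
subsample of 100 runs for Mean-likelihood evaluation is the reduced setting
used by the recovery studies and tests. Ensembles are deterministic given
(package seed, trial index); the same per-trial random stream is reused for
every γ on the fitting grid (common random numbers), so likelihood differences
along the grid reflect γ rather than Monte-Carlo noise. An exact oracle
enumerates all (n−1)ⁿ join vectors for n ≤ 8 and is used to validate the
sampler (total-variation distance < 0.01 at n = 6).

## Observer models

- **CoS Mode** (4 free parameters: γ, β₀, β₁, σ_mode): `C*` is the heaviest
  cluster's centroid (exact ties broken uniformly at random); the trial
  likelihood is the R-component Gaussian mixture over the ensemble, evaluated
  by log-sum-exp.
- **Representation posterior**: given an observed Mode response, run j gets
  weight ∝ exp(−(y_mode − C*_j)²/2σ_mode²). The response is compared with the
  raw C*_j, not β₀ + β₁C*_j; whether the linear transform belongs inside this
  selection stage is ambiguous in the model's source, and the printed form is
  implemented (a documented switch is not offered — lesioning the prior
  entirely is, see below). The σ_mode and γ used here are the subject's
  best-fit Mode values.
- **CoS Mean** (5: α, σ_LI, β₀, β₁, σ_mean): subjective weights
  θ_k ∝ w_k^α / Σ_j w_j exp(−(c_j−c_k)²/2σ_LI²), M* = Σ c_k θ_k; the likelihood
  mixes M*_j over runs with the representation-posterior weights.
- **Lesions**: w/o PT pins α = 1; w/o LI drops the denominator; w/o LI&PT has
  θ = w (and exactly reproduces the sample mean); w/o Prior replaces the
  representation posterior by a uniform 1/R (testing the shared-representation
  assumption). The Mean battery is {CoS, w/o LI, w/o PT, w/o LI&PT, w/o Prior,
  SW} with 5/4/4/3/5/4 free parameters.
- **Subjective weighting (SW)** (4: σ_LI, β₀, β₁, σ_mean): the lateral
  inhibition applied to the 70 raw samples (the power transform cancels on
  equal weights); a single-Gaussian likelihood.
- **DPMM ideal observer**: G ~ DP(Uniform[a,b], α), shared precision
  τ ~ Gamma(α_τ = 1, β_τ), β_τ ~ Gamma(1,1), α ~ Gamma(α_c, 1). Inference by
  Gibbs sampling with the auxiliary-component update (m = 3 auxiliary tables)
  for the non-conjugate uniform base, truncated-Gaussian conditionals for
  cluster means (rejection sampling; the base interval [−20, 20] cm is wide
  relative to posterior SDs so acceptance is ≈ 1, with clipping as a last
  resort), gamma conditionals for τ and β_τ, and the beta-augmentation update
  for α. Four chains of 500 iterations, first 250 discarded (1000 retained
  draws) by default; 2 × 150 in the reduced setting. Per draw, the mixture
  mean is Σ (n_k/N) μ_k and the mixture mode the argmax of the mixture density
  on a 0.01 cm grid (ties to the lowest coordinate); the observer's estimates
  average both over retained draws. Mode-task fitting grid-searches α_c; the
  Mean task reuses the subject's Mode-task α_c (3 free parameters). The
  sampler's α-update was validated by a prior-invariance (Geweke-style) chain.
- **Moment regressions**: Y = β₀ + Σ β_j Z_j + noise with predictors from
  {true mode, true mean, true skewness} (GT uses the task's own statistic;
  variance is excluded because all stimuli share one SD). Their MLE is OLS
  with the biased σ̂ (computed in closed form); they predict strictly unimodal
  response distributions, which is what the multimodality analyses exploit.

## Fitting and comparison

Continuous parameters: bounded Nelder-Mead from Latin-hypercube starts
(default 10 starts; 3 in the reduced setting), σ bounded below at 10⁻³ cm to
guard the likelihood against zero-noise degeneracy, β₁ ∈ [0, 2], β₀ ∈ ±5 cm,
α ∈ [0.05, 3], σ_LI ∈ [0.1, 30] cm. Stochastic parameters: γ grid 0.02–2.00
(step 0.02; 18-point grid in the reduced setting) and α_c grid 0.10–3.00
(step 0.10; {0.5, 1.5, 3.0} reduced). The CoS Mean likelihood is optimised as
a profile: an outer search over (α, σ_LI) — which alone determine the M*
values, recomputed by a JIT-compiled kernel over the ragged cluster arrays —
with the response parameters re-optimised cheaply inside each evaluation.

Comparison: AICc = 2·NLL + 2k + 2k(k+1)/(n−k−1) per subject with n the
subject's trial count; per-subject ΔAICc against the subject's best model,
summed over subjects. Group selection: variational Dirichlet random-effects
model over model frequencies (log evidence ≈ −AICc/2), exceedance
probabilities by 10⁵ Dirichlet draws, Bayes omnibus risk from the
equal-frequency null, PXP = (1−BOR)·EP + BOR/K. The sampled exceedance
probabilities are validated against the closed-form Beta tail for K = 2.

The response-multimodality check fits full-covariance bivariate Gaussian
mixtures (1–3 components, EM with 20 starts, tolerance 10⁻⁸) and selects by
ICL = BIC + 2 × assignment entropy; multimodality is declared when the
selected ICL beats the single-component ICL.

## Synthetic cohorts and what the tests show

Simulated subjects share the real designs' stimuli; per-subject response
parameters are jittered around the identity transform (β₀ ~ U(−0.5, 0.5),
β₁ ~ U(0.9, 1.1), σ_mode ~ U(1, 2) cm, σ_mean ~ U(0.8, 1.5) cm, and for CoS
generators α ~ U(0.6, 0.8), σ_LI ~ U(3, 5) cm). One clustering run per trial
is shared between the two tasks, matching the shared-representation
assumption. Parameter- and model-recovery studies use γ = 0.5 and 8 subjects
at E1 scale; behavioural-signature and histogram summaries use γ = 2.0, where
clusters track whole mixture components, with 16 subjects. The generator
emulates the stimulus statistics and the observer's decision process, not
perceptual encoding noise, lapses, sequential effects or motor dynamics —
passing tests therefore validate the algorithms and their identifiability, not
claims about real subjects.

Known behaviour of the estimators at this scale: the per-subject γ likelihood
is shallow (MLEs scatter over roughly ±0.15 around a generating 0.5 even with
R = 3000), so recovery is assessed on the cohort mean of γ̂; and the L1
distance between the DPMM posterior-average density and the diffusion KDE of
the same 70 samples is typically 0.10–0.22 (mean ≈ 0.16) — the two estimators
are far closer to each other than either is to the generating density
(≈ 0.28), but their residual disagreement is irreducible at N = 70.

## Numerical conventions

Log-sum-exp throughout for mixture likelihoods; densities renormalised by the
trapezoid rule; sample SD uses the n−1 denominator; exact weight ties in the
Mode readout are broken uniformly via a sub-resolution jitter (weights are
multiples of 1/70, so genuinely different weights can never be reordered);
KDE argmax ties resolve to the lowest grid coordinate. All randomness flows
from explicit integer seeds through `numpy.random.SeedSequence` streams keyed
by (purpose, trial); identical seeds reproduce ensembles, MCMC draws and whole
reports bit-for-bit.

## Limitations

No circular statistics for orientations; a single shared DPMM precision τ (no
per-cluster variances); no split-merge MCMC moves or formal convergence
diagnostics; group selection consumes −AICc/2 as the evidence approximation;
the ICL mixture settings (covariance structure, starts) are package defaults;
human-data analyses (ANOVAs, post-hoc tests) are out of scope.
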