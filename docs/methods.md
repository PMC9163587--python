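# Methods

## The orientation model

White-matter fibres behave magnetically like radially symmetric tensors:
the apparent susceptibility a single-orientation QSM reconstruction assigns
to a voxel varies with the fibre-to-field angle θ as
χ_app(θ) = (χ∥ − χ⊥)·cos²θ + χ₀. Aggregated over a tract ROI, the package
treats the same law as an ordinary least-squares problem
χ_app = δχ·cos²θ + χ_iso with the tract-level apparent anisotropy δχ as
slope and the isotropic AMS χ_iso as intercept. All susceptibilities are
handled in ppb; θ is accepted in degrees on [0°, 90°], with antipodal fibre
symmetry (θ ≡ 180° − θ) assumed folded at the interface. Per-subject OLS
fits are diagnostics; cohort-level inference always goes through the
multilevel model so that subject-level estimation noise is propagated.

Identifiability of δχ depends entirely on the spread of cos²θ inside the
ROI: in tracts whose fibres run almost perpendicular to B₀ (splenium,
optic radiation) cos²θ spans only ~0–0.25 and single-subject δχ estimates
are noisy, while χ_iso (the value at θ = 90°) remains well determined.
This asymmetry propagates through everything downstream and is reproduced,
deliberately, by the synthetic generator.

## The multilevel model

For one ROI, voxel v of subject s follows

    χ_app^v = [χ_iso^s + β_iso·AO_s + τ_iso·DD_s + λ_iso·LL_s]
            + [δχ^s   + β_δχ·AO_s + τ_δχ·DD_s + λ_δχ·LL_s]·cos²θ_v + ε_v,

with ε ~ N(0, σ_n), χ_iso^s ~ N(μ_iso^coh, σ_iso^coh) and
δχ^s ~ N(μ_δχ^coh, σ_δχ^coh). Covariates: AO is age at examination (HC) or
age at disease onset (MS), referenced to 30 years and scaled by 10 years;
DD is disease duration in decades and LL the ROI lesion-load fraction,
both structurally zero for controls — consequently τ and λ exist only for
the MS cohort and are simply not parameters otherwise. The ageing slope β
is shared by the cohorts. Each ROI is fitted independently.

χ_app is standardized (pooled mean/SD within the ROI) before fitting and
every posterior draw is rescaled back to ppb, so priors can be stated on a
unitless scale: Normal(0, 1) for cohort means — symmetric about zero on
purpose, since whether apparent anisotropy can be negative is part of what
the analysis must be able to report — and Half-Normal(1) for all SDs.
Covariate-effect priors are additionally autoscaled by the covariate's
standard deviation (prior SD = `effect_prior_scale` / sd(covariate)), the
convention popularized by regression front-ends such as rstanarm. Without
autoscaling, a unit-scale prior on the lesion-load coefficient (covariate
SD ≈ 0.1) is in fact strongly informative: it shrinks λ towards zero and
the unabsorbed average lesion effect re-appears as a bias in μ_δχ^MS and
hence in the effect size. All prior scales are configurable in
`ModelSpec`.

### Inference: collapse, then sample only the scales

Given the five scale parameters (four cohort SDs and σ_n) the model is
linear-Gaussian in everything else. The sampler exploits this twice:

1. each subject's (intercept, slope) pair is integrated out with a 2×2
   Woodbury identity, using only six sufficient statistics per subject
   (n, Σc, Σc², Σy, Σyc, Σy² with c = cos²θ), so likelihood cost is
   independent of voxel count;
2. the location parameters (cohort means, β, τ, λ) are integrated out with
   one rank-L update (L ≈ 10), leaving a collapsed posterior over the
   scales alone.

The collapsed 5-dimensional posterior is sampled by independence
Metropolis–Hastings. The proposal is built on the σ scale (not log σ):
for weakly identified anisotropy SDs the posterior approaches a bounded
plateau as σ → 0, which a σ-scale proposal covers with bounded importance
ratios, whereas any log-scale proposal under-covers that tail and the
chain sticks. The proposal is a defensive mixture of a multivariate t
(df = 6) fitted by a Laplace step and refined by two rounds of truncated
importance-weighted moment matching, plus a 15% wide heavy-tailed
component (9× covariance, df = 3). Because independence proposals do not
depend on the current state, each chain needs exactly one vectorized
density evaluation; chains are independent restarts. Location parameters
are then drawn exactly from their Gaussian conditional per retained scale
draw, and subject effects from their exact bivariate-normal conditionals —
these two steps add no Monte-Carlo bias and show split-R-hat ≈ 1.000 by
construction. An affine-invariant ensemble sampler (emcee) is available
via `ModelSpec(sampler="ensemble")` as an independent backend.

Defaults: 4 chains × 3000 kept draws (200 discarded), thinned to 1000 per
chain; a full ROI fit at 153 subjects × 500 voxels takes roughly one
second on one CPU, with worst observed split-R-hat ≈ 1.003 across stress
runs. Non-convergence (split-R-hat above 1.01 on any parameter) raises a
`RuntimeWarning` and flags the results object; it never fails silently.
When every scale is fixed (degenerate analytic checks) the posterior is
exactly Gaussian and draws are i.i.d. conditionals with no MCMC at all.

Diagnostics: split-R-hat uses the classic pooled/within variance-ratio
with each chain split in half; values below 1, an artefact of the
finite-sample correction, are clipped to exactly 1.0. Effective sample
sizes come from arviz.

## Posterior summaries

* **HDI**: sliding window over the sorted draws — the narrowest interval
  containing ⌈mass·n⌉ consecutive order statistics; among ties the lowest
  start wins (the uniform-density edge case is positionally ambiguous).
* **MAP**: mode of a binned Gaussian-kernel density estimate (4096 bins
  over the 0.1–99.9 percentile range, Silverman bandwidth), refined by a
  local parabola fitted to the log-density within ±2 bandwidths of the
  grid argmax — exact for a Gaussian peak and suppressing flat-top argmax
  noise. Accuracy at 10⁶ draws: within ±0.035 of the true mode for normal
  and lognormal test densities.
* **P(>0)**: fraction of draws strictly above zero; draws equal to zero
  count as not-above.
* **Effect size**: η = (μ^MS − μ^HC)/√[(σ²_MS + σ²_HC)/2] evaluated per
  joint posterior draw for the iso and δχ components, preserving the
  μ–σ dependence; reported as its own MAP/HDI/tail mass.

## Synthetic cohort generator

The generator emulates the study conditions the analysis targets, and its
defaults are fixed at those conditions: 64 HC and 89 MS subjects, three
ROIs, 500 voxels per subject per ROI.

* **Angles**: axes are drawn from a Watson distribution (density ∝
  exp(κ(μᵀx)²)) about a mean fibre direction at a set angle to B₀, via an
  exact rejection sampler (truncated-exponential envelope, acceptance ≥
  ~50% at every κ); θ is the angle of the sampled axis to B₀, folded to
  [0°, 90°]. κ = 0 reproduces the sin θ density of uniform axes; κ = ∞ is
  the degenerate point mass. Defaults: SCC mean 90°, κ = 40 (central 95%
  of θ spans ~14° — well inside the narrow one-third-of-range regime);
  OR mean 90°, κ = 12 (~27°); SLF mean 45°, κ = 1 (broad).
* **Covariates**: HC ages truncated-normal 35 ± 10 on [24, 66] years; MS
  onset ages truncated-normal 29 ± 10 on [18, 55]; disease duration
  lognormal with median 9 years clipped to [1, 32] (sample median lands in
  [7, 11]); age = onset + duration. Lesion loads are zero-inflated Beta
  per ROI with the optic radiation most affected (P(0) = 0.15,
  Beta(1.5, 12)); support is [0, 1] by construction.
* **Susceptibilities**: cohort means use the scenario values
  δχ^HC = 27 / 21 / −30 ppb and χ_iso^HC = −40 / −35 / −15 ppb for
  OR / SCC / SLF; the OR cohort difference of −6 ppb at pooled σ_δχ =
  10 ppb encodes a true effect size of −0.6. Covariate effects sit in the
  reported plausible ranges (e.g. β_iso = +3…+5 ppb/decade, τ_δχ^MS = −10
  ppb/decade in SCC, λ_δχ^MS = −30 ppb per unit lesion-load fraction in
  OR).
* **Noise**: i.i.d. Gaussian voxel noise, homoscedastic within ROI and
  shared across cohorts, default SD 10 ppb. No voxel-level noise magnitude
  is published for this kind of data; the default was calibrated so that
  the decile-curve spread looks plausible and the OR effect-size posterior
  reaches the concentration reported for the real cohorts (≈1% posterior
  mass above zero at a −0.6 effect). It remains an arbitrary, configurable
  choice.

What passing tests on this generator do **not** show about real data: the
generator contains no spatial voxel correlation, no dipole-inversion
streaking or orientation-dependent reconstruction bias (a structured
θ-correlated artifact can be injected explicitly via
`inject_orientation_artifact`), no registration or segmentation error in
θ/FA/PQ, no heteroscedasticity across subjects, and lesion load is a
scalar covariate rather than geometry. Parameter recovery here validates
the statistical machinery, not the physics of single-orientation QSM.

## Masking

Structuring elements are metric: an offset belongs to the sphere iff its
physical displacement (offset × voxel size, Euclidean) is within the
radius, so anisotropic grids behave correctly; at 1 mm isotropic voxels
the r = 2 mm sphere has 33 offsets and the r = 1 mm sphere 7. Erosion
treats out-of-volume as background (conservative at edges). The
crossing-fibre rule retains voxels with FA ≥ 0.6 **and** PQ ≤ 0.3 — the
reading that removes both low-anisotropy and crossing-fibre voxels — with
a closed (boundary-inclusive) acceptance region. NAWM = WM minus the
lesion mask dilated by 1 mm; lesion load = |ROI ∩ lesion| / |ROI|, raising
on an empty ROI. Whether the FA/PQ filter runs before or after ROI
intersection is not fixed by the pipeline; the filter is a pure
row-filter on voxel tables and defaults to filter-last.

## Numerical and edge-case choices

* Degenerate decile bins: remainder voxels go to the lowest bins; ties in
  θ are broken by stable sort order.
* Standardization uses the population SD (ddof = 0); zero-variance ROIs
  raise.
* `log_joint_density` returns −∞ (never NaN) for non-positive scales.
* Rank-deficient per-subject designs (a single distinct angle) raise with
  an explicit message that δχ is unestimable.
* Fixed scale parameters are specified in data units and converted to the
  standardized scale internally; `mu_prior_scale = inf` gives flat priors
  on the cohort means (used by the conjugate closed-form checks).
* Seeds: every public sampling entry point takes a seed; child seeds are
  derived through `numpy.random.SeedSequence`, and identical seeds yield
  byte-identical outputs.

## Problem sizes used in the shipped checks

The recovery study runs 20 replicate cohorts at the full default
conditions (64/89 subjects, 3 ROIs, 500 voxels/ROI) — the marginalized
likelihood makes fit cost independent of voxel count, so no down-scaling
is needed — and checks 95% HDI coverage of the ten population-level
location parameters per ROI (observed ≈ 95%; the shipped check accepts
≥ 85% to allow Monte-Carlo error around nominal coverage) and split-R-hat
< 1.01 everywhere. Effect-size recovery at this sample size is
intrinsically noisy: the MAP of the η posterior scatters around the truth
with SD ≈ 0.25–0.35, composed of finite-cohort realization noise
(SD ≈ 0.17), covariate-effect trade-offs, and MAP extraction noise, so
individual replicates can miss a ±0.3 band even with a correct model.

## Known limitations

* The sampler's independence proposal is adapted once before sampling; a
  pathological multi-modal scale posterior (not observed in any tested
  configuration, and unexpected for this likelihood) would reduce
  acceptance and show up as elevated split-R-hat rather than being
  repaired automatically.
* τ and λ are estimated only where the MS cohort provides variation in
  duration and lesion load; with near-constant covariates their posteriors
  return the (autoscaled) prior.
* The voxel likelihood ignores spatial correlation, so posterior SDs are
  calibrated for the generator's i.i.d. noise, not necessarily for real
  QSM noise fields.
* Per-subject OLS `residual_sd` uses n − 2 degrees of freedom and is
  reported as a diagnostic only; it does not enter the hierarchical fit.
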