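# amsa — apparent magnetic susceptibility anisotropy from single-orientation QSM

Quantitative susceptibility mapping (QSM) assigns each brain voxel a scalar
*apparent* magnetic susceptibility (AMS, χ_app). In white matter the value
depends on the angle θ between the local fibre direction and the main field
B₀: for a radially symmetric fibre susceptibility tensor,

    χ_app(θ) = (χ∥ − χ⊥)·cos²θ + χ₀.

Measuring the tensor requires scanning the head at several orientations,
which is clinically impractical. This package implements the
single-orientation alternative: within a white-matter tract, the natural
spread of fibre-to-field angles turns the same relation into a regression

    χ_app(θ) = δχ·cos²θ + χ_iso,

whose slope δχ (*apparent* magnetic susceptibility anisotropy, a putative
myelin marker) and intercept χ_iso (isotropic AMS, absorbing iron and other
orientation-independent contributions) are estimated per subject and tract.
Cohort comparisons — here healthy controls (HC) versus relapsing-remitting
multiple sclerosis (MS) patients — use a Bayesian multilevel model: voxels
within subjects, subject-level (χ_iso, δχ) drawn from cohort normal
distributions, and population-level effects of ageing (per decade from a
30-year reference), disease duration (per decade, MS only) and ROI lesion
load (fraction, MS only), fitted independently for each tract (optic
radiation OR, splenium SCC, superior longitudinal fascicle SLF). Posteriors
are summarized by MAP estimates, 95% highest-density intervals (HDI) and
the per-draw standardized cohort difference

    η = (μ^MS − μ^HC) / √[(σ²_MS + σ²_HC)/2].

Patient data are not public, so the package ships a synthetic cohort
generator that reproduces the statistical structure of the study (cohort
sizes, covariate distributions, tract-specific Watson angle profiles,
cos²-law voxels) and is used by every test. A masking module implements the
voxel-selection rules (metric sphere erosion/dilation, FA/peak-quotient
crossing-fibre exclusion, NAWM construction, lesion-load fractions) for
NIfTI volumes.

## Worked example

```python
import amsa

cfg = amsa.default_config(seed=1)            # 64 HC / 89 MS, OR+SCC+SLF
voxels, subjects, truth = amsa.generate_cohort_dataset(cfg)

model = amsa.TractAnisotropyModel.from_tables(voxels, subjects, "OR")
res = model.fit(seed=1)
print(res.summary().round(2).to_string(index=False))
es = res.effect_sizes()["eta_dchi"]
print(f"eta_dchi MAP {es.map_estimate:.2f}, "
      f"95% HDI ({es.hdi_low:.2f}, {es.hdi_high:.2f}), "
      f"P(>0) {es.prob_above_zero:.3f}")
```

prints (abridged)

```
roi      parameter    map  hdi_low  hdi_high  prob_above_zero
 OR      mu_iso_HC -40.12   -41.86    -38.60             0.00
 OR     mu_dchi_HC  26.30    21.65     30.13             1.00
 OR      mu_iso_MS -39.15   -41.62    -36.97             0.00
 OR     mu_dchi_MS  21.01    14.21     26.71             1.00
 OR       beta_iso   3.22     2.14      4.39             1.00
 OR  sigma_dchi_HC  12.75     9.80     15.65             1.00
 OR       noise_sd   9.99     9.94     10.04             1.00
eta_dchi MAP -0.45, 95% HDI (-1.09, 0.17), P(>0) 0.081
```

Read: in the optic radiation the age-corrected mean apparent anisotropy for
this simulated cohort is about 26 ppb in controls and 21 ppb in patients;
isotropic AMS sits near −40 ppb and increases with age by ~3 ppb per
decade; the cohort difference in δχ corresponds to a standardized effect
size around −0.5 with ~8% posterior mass above zero. Values are in ppb;
the model samples on a standardized scale internally and rescales every
draw back.

A thin CLI mirrors the pipeline: `amsa simulate`, `amsa mask`,
`amsa fit-subjects`, `amsa fit-model`, `amsa report`.

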