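# Methods

This note records the models behind `nervemorph`, the calibrated
constants and why they hold their values, the numerical choices in the
two bespoke estimators, and what the synthetic data can and cannot show.

## The synthetic cohort and fibre generator

**Cohort.** Ages are normal (mean 92.0, SD 5.4 years) left-truncated at
65; sex is Bernoulli (72.1% female); vascular covariates (hypertension
67.1%, smoking 35.7%, BMI 25.5 ± 4.3 kg/m², GFR 59.9 ± 16.0
ml/min/1.73 m², 0–4 vascular diseases ~ Binomial(4, 0.245)) are drawn
independently of each other and of fibre morphology. Per-participant
fibre counts are log-normal with mean 5387 and SD 3436, clipped to
[299, 19892]. Per-participant density is log-normal with mean 4993.4
fibres/mm² (log-SD 0.399) and never depends on age: the age-null for
density holds by construction, which is exactly the property the
analysis layer is expected to detect.

**Fibres.** Axon diameters are log-normal. The pooled log-scale SD
0.6215 is split into a within-person part (0.5754) and a between-person
log-scale random effect (SD 0.235); the two compose to the same pooled
marginal, while the person effect gives the person-mean fibre diameter
its empirically sensible spread (~0.9 µm, and with it an OLS age-slope
SE of ~0.014 µm/yr at n = 140). Myelin thickness is

    t = max(0, c0 + 0.5·min(a, 4) + 0.125·clip(a − 4, 0, 4) + ε),
    ε ~ N(0, σ_n²),

a continuous piecewise-linear law (slope 0.5 µm/µm below 4 µm, 0.125
from 4–8 µm, plateau above 8 µm) with constant-SD noise clipped at
zero. Exactly-zero thickness yields g = 1 fibres (~4% at the defaults),
emulating fibres an automated segmentation reports as unmyelinated.

**Ageing mechanism.** A participant of age A has axon scale multiplied
by `exp(−k·(A − 92))`, `k = 0.011046`/yr: older participants have
proportionally shrunken diameter tails but unchanged counts and
density — atrophy, not loss. One parameter simultaneously produces the
negative age slopes for fibre/axon/myelin averages and the
preferential depletion of the > 8 µm bins in the compositional model.

**Calibration.** `scripts/calibrate_generator.py` fixes the constants
once. Pooled myelin moments under zero-clipped noise have the closed
form `E[max(0, m+σε)] = mΦ(m/σ) + σφ(m/σ)`, integrated over the axon
law by Gauss–Hermite quadrature; the pooled g-ratio mean uses a
fixed-seed Monte-Carlo integral; `k` solves a 1-D root-finding problem
for the population OLS slope of expected person-mean fibre diameter on
age, with ages integrated over the truncated normal. Resulting pooled
marginals: axon 2.05 µm (SD 1.41), myelin 1.42 µm, fibre 4.89 µm,
g-ratio 0.443. The share of myelin variance explained by axon size
lands at ≈ 0.43: with this noise model it cannot be pushed to ~0.57
without dragging the g-ratio mean below its target band, and the
marginal means were given priority. That trade-off is a known
limitation of the constant-SD clipped-noise choice.

**Rendering.** Fibres are drawn as non-overlapping axon disks with
myelin annuli (rejection-sampled placement, largest first, 0.3 µm
guard margin), exact uint16 label masks sharing labels between axon and
myelin, and a grayscale image (background 200, axoplasm 170, myelin 60,
additive Gaussian noise SD 8 on a 0–255 scale). Touching or
non-circular fibres, staining artifacts, vessels and unmyelinated axons
are deliberately out of scope, so segmentation performance on these
images says nothing about real histology — the renderer exists to give
the mask→metrics path a ground truth with a known quantization error
(diameters recoverable within 2 pixel sizes).

## Morphometry

All metrics derive from areas via equivalent diameters, so
`fibre = axon + 2·thickness` is an algebraic identity, not an
approximation. Invalid records (negative thickness, g > 1, non-finite,
non-positive axon area) are filtered, with g = 1 kept valid by default;
the three published exclusion rules (g = 1, fibre < 1 µm, axon
< 0.8 µm) are pipeline-level sensitivity options instead. Mask
extraction labels axon components with 8-connectivity and assigns each
myelin pixel to the nearest axon component by watershed on the distance
transform (deterministic, exact for disjoint annuli); components
touching the field border have censored areas and are excluded from
metrics by default (`include_border=True` overrides). Density divides
the fibre count by the full analysed mask area — no attempt is made to
subtract non-fibre intrafascicular space.

## Aggregation

Person averages are arithmetic means over valid fibres. Subsampling is
uniform without replacement, 100 fibres per participant, deterministic
per (seed, participant id) so participant order cannot change the
draw. Diameter bins are half-open with 2.0 µm belonging to bin II.
Zero percentages are replaced multiplicatively by half the smallest
observable proportion, `0.5·(100/n_i)` (capped so replacement mass
cannot exceed half the composition in degenerate tiny-n cases), with
the other bins rescaled before taking `ln(p_k/p_1)`; replacement counts
are logged in the result's attrs.

## The penalized-spline mixed smoother

Model: `y = f(x) + u_g + ε`, `u_g ~ N(0, τ²)`, f a cubic B-spline with
20 interior knots at x-quantiles and a second-derivative penalty
(Gram matrix assembled exactly by per-span Gauss–Legendre quadrature).
The spline coefficients and stacked random intercepts solve one
penalized least-squares system; λ and the variance ratio σ²/τ² are
chosen by maximizing the profiled REML criterion on a coarse log-grid
followed by bounded golden-section refinement, coordinate-wise, three
sweeps (tolerance 1e−4 on the log-parameters). EDF is the trace of the
smoother matrix restricted to the spline block; the penalty null space
(dimension 2) makes the λ→∞ limit exactly the OLS line, which the tests
exploit as an oracle. Derivatives come from the analytic B-spline
derivative, never finite differences. 20 knots rather than a sparser
basis: quantile placement puts almost no knots beyond the ~90th
percentile of axon diameter, and a 12-knot basis visibly smears the
slope change at 4 µm (biasing the 1–4 µm mean derivative low and the
4–8 µm one high); 20 knots resolve it with REML still controlling
wiggliness (EDF ≈ 8 on default data).

## The heteroscedastic Gaussian mixed regression

Model: `y_i = x_i'β + u_g(i) + ε_i`, `ε_i ~ N(0, exp(2 z_i'γ))`,
`u_g ~ N(0, τ²)` — a location-scale regression with identity link for
the mean, log link for the SD, and a participant random intercept. The
exact marginal likelihood is evaluated per group through the Woodbury
identity (cost linear in n; no covariance matrix is ever formed) and
maximized over (β, γ, log τ) by L-BFGS-B with analytic gradients, from
an OLS / log-|residual|-regression / moment start plus three seeded
jittered restarts; bounds keep γ in ±30 and log τ in [−12, 6], and
off-scale line-search points return a large finite value rather than
overflowing. Wald SEs and two-sided normal p-values come from the
numerical Hessian at the optimum; a singular Hessian flags SEs NaN. A
dense multivariate-normal evaluation on small instances is the
independent likelihood oracle (agreement to 1e−6 required in tests).
Nested dispersion designs are compared by likelihood ratio, with the
larger model warm-started from the embedded smaller optimum so the LR
statistic cannot go negative by optimization failure.

**Study layouts.** The compositional model stacks the five reference
log-ratios per participant; fixed effects are centred age (age − 92),
sex, category dummies (reference: the 2–4 µm ratio) and age×category
interactions; the dispersion design is intercept + category dummies.
The g-ratio model works on the 100-fibre subsamples with bin dummies
(reference: ≥ 10 µm) and age×bin interactions, dispersion intercept +
bin dummies. Centring age changes intercept/main-term bookkeeping only,
not the interaction coefficients that the recovery experiments target.
The published tables do not report dispersion or random-intercept
parameters, so the recovery simulations fix plausible values (ALR:
category residual SDs ≈ 0.45–0.7, τ = 0.30; g-ratio: bin residual SDs ≈
0.09–0.18, τ = 0.02) consistent with the printed SEs; recovery is
checked on the mean-submodel coefficients.

No multiple-testing correction is applied anywhere, matching the
analysis the pipeline mirrors.

## Problem sizes and reproducibility

Default analyses use the full simulated cohorts (~750 000 fibres);
recovery experiments use 20 replicates; the smoother runs on the
14 000-row subsample; the pooled-marginal checks pool four cohorts
(~3 × 10⁶ fibres). A single global seed fans out to per-stage child
seeds via `numpy.random.SeedSequence`, so identical seeds give
bit-identical cohorts, placements and CSVs, and any stage can be rerun
in isolation.

## Known limitations

* The generator reproduces published *marginals and association
  structure*, not the unknown joint law of real nerves; passing
  recovery tests shows the estimators are correct for data of this
  form, not that real tibial nerves follow these laws.
* Whether the real age effect is purely multiplicative on the axon
  scale is not knowable from summary statistics; it is a modelling
  choice, flagged, not asserted.
* Variance-explained for myelin (~0.43) undershoots the published 57.4%
  (see Calibration above).
* The classical threshold segmentation is for synthetic contrast only.
* Covariates are independent of morphology, so covariate adjustment in
  the OLS ladder barely moves estimates — by design, mirroring the
  published adjustment pattern, but it means confounding behaviour
  cannot be studied with the defaults.
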