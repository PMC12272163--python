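# nervemorph

Morphometry of myelinated peripheral-nerve fibres and its association
with age, packaged as a fully synthetic, download-free pipeline.

Postmortem studies of the tibial nerve in very old adults quantify
hundreds of thousands of myelinated fibres per cohort from segmented
cross-sections and ask how fibre calibre changes in late life: whether
older age means *fewer* fibres (loss) or *smaller* fibres (atrophy).
`nervemorph` reproduces that analysis chain end to end for
methodologists and students of quantitative neuropathology:

1. **Synthetic data** — cohorts of ~140 nonagenarian decedents with
   realistic covariates; per-participant fibre populations with a
   right-skewed log-normal axon-diameter law, a continuous
   piecewise-linear axon→myelin relation, and an age effect acting as
   multiplicative shrinkage of the diameter scale (atrophy, not loss);
   optionally rendered cross-section images with exact axon/myelin
   label masks.
2. **Morphometry** — from masks or area tables, the equivalent-diameter
   formulas: axon diameter `2·√(A_axon/π)`, fibre diameter
   `2·√((A_axon+A_myelin)/π)`, g-ratio `d_axon/d_fibre`, myelin
   thickness `(d_fibre−d_axon)/2`; validity filtering (negative
   thickness or g > 1) and fibre density (count/mm²).
3. **Aggregation** — person-specific averages, seeded 100-fibre
   subsamples, six half-open diameter bins
   `[0,2), [2,4), [4,6), [6,8), [8,10), [10,∞)` µm with compositional
   percentages and reference log-ratios `ln(p_k/p_1)`.
4. **Inference** — Spearman correlations; covariate-ladder OLS; a
   penalized cubic-spline mixed smoother (REML-selected smoothing,
   participant random intercept, analytic derivatives) for the
   nonlinear axon–myelin relation; and a heteroscedastic Gaussian mixed
   regression (identity-link mean, log-link SD, participant random
   intercept, exact marginal ML) for the compositional log-ratios and
   the g-ratio × diameter-group interactions.

## Worked example

```python
import numpy as np
import nervemorph as nm

cfg = nm.CohortConfig(seed=7)                      # the default profile
participants, fibres = nm.sample_cohort_fibres(cfg)
areas = nm.fibres_to_area_table(fibres)
metrics = nm.fibre_metrics_table(areas)
kept, n_excluded = nm.validity_filter(metrics)
print(f"fibres measured: {len(metrics)}  excluded: {n_excluded}")

print(f"pooled means: fibre {kept['fibre_diameter_um'].mean():.2f} um, "
      f"axon {kept['axon_diameter_um'].mean():.2f} um, "
      f"myelin {kept['myelin_thickness_um'].mean():.2f} um, "
      f"g-ratio {kept['g_ratio'].mean():.3f}")

person = nm.person_averages(kept, participants)
person["sex"] = (person["sex"] == "female").astype(float)
fit = nm.fit_ols(person["mean_fibre_diameter_um"],
                 person[["age_at_death", "sex"]])
print(f"age slope on person-mean fibre diameter: "
      f"{fit.params['age_at_death']:.4f} um/yr "
      f"(SE {fit.bse['age_at_death']:.4f})")

sub = nm.subsample_fibres(kept, 100, seed=7)
sm = nm.fit_spline_mixed(sub["myelin_thickness_um"],
                         sub["axon_diameter_um"],
                         groups=sub["participant_id"])
print(f"spline smooth: EDF {sm.edf:.1f}; mean d(myelin)/d(axon) "
      f"{sm.derivative(np.linspace(1, 4, 61)).mean():.3f} um/um on 1-4 um")
```

prints

```
fibres measured: 719402  excluded: 0
pooled means: fibre 5.00 um, axon 2.11 um, myelin 1.44 um, g-ratio 0.443
age slope on person-mean fibre diameter: -0.0567 um/yr (SE 0.0151)
spline smooth: EDF 8.2; mean d(myelin)/d(axon) 0.468 um/um on 1-4 um
```

That is: ~720 000 fibres for one simulated cohort, pooled marginals near
the calibrated targets (fibre 4.9 µm, axon 2.0 µm, myelin 1.4 µm,
g-ratio 0.45), a clearly negative age slope for this cohort draw (the
expected value across cohorts is −0.041 µm/yr), and a spline smooth
whose ~8 effective degrees of freedom and ~0.5 µm/µm slope below 4 µm
reflect the piecewise axon–myelin law.

The same run is available from the shell:

```bash
nervemorph analyze --seed 7 --out results/
nervemorph render --seed 4 --n-fibres 80 --out results/section
nervemorph measure --axon-mask results/section.axon.tif \
    --myelin-mask results/section.myelin.tif --pixel-size 0.1 \
    --out results/fibres.csv
```

`analyze` writes person-level and model CSVs, distribution and
age-scatter figures, a sensitivity table for the three exclusion rules
(g = 1, fibre < 1 µm, axon < 0.8 µm), and a manifest with seeds and
stage-by-stage record counts.

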