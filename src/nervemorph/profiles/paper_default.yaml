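n_participants: 140
age_mean: 92.0
age_sd: 5.4
age_min: 65.0
p_female: 0.721
fibre_count_logmean: 8.421074653064123
fibre_count_logsd: 0.5842418499498504
fibre_count_min: 299
fibre_count_max: 19892
axon_logmean: 0.525761
axon_logsd: 0.575409
person_scale_logsd: 0.235
tail_shrink_per_year: 0.011046
myelin_intercept: 0.429983
myelin_slopes:
- 0.5
- 0.125
myelin_breakpoints:
- 4.0
- 8.0
myelin_noise_sd: 0.633575
density_target: 4993.4
density_logsd: 0.3993276474679046
hypertension_prev: 0.671
smoking_prev: 0.357
bmi_mean: 25.5
bmi_sd: 4.3
gfr_mean: 59.9
gfr_sd: 16.0
vascular_p: 0.245
seed: 0
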