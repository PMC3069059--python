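# Scenario 1: additivity and linearity (true propensity model has main
# effects only). Covariate indices are 1-based (w1..w10).
# w1-w4 confound exposure and outcome; w5-w7 affect exposure only;
# w8-w10 affect outcome only. Six covariates are dichotomized at the
# latent mean; correlations are specified on the latent normal scale.
scenario_id: 1
n_covariates: 10
covariate_roles:
  confounder: [1, 2, 3, 4]
  exposure_only: [5, 6, 7]
  outcome_only: [8, 9, 10]
correlation_pairs:
  - [1, 5, 0.2]
  - [2, 6, 0.9]
  - [3, 8, 0.2]
  - [4, 9, 0.9]
dichotomize: [1, 3, 5, 6, 8, 9]
dichotomize_cut: 0.0
exposure_intercept: 0.0
exposure_main_coefs: [0.8, -0.25, 0.6, -0.4, -0.8, -0.5, 0.7, 0.0, 0.0, 0.0]
exposure_interaction_terms: []
exposure_quadratic_terms: []
outcome_intercept: -3.85
outcome_coefs: [0.3, -0.36, -0.73, -0.2, 0.0, 0.0, 0.0, 0.71, -0.19, 0.26]
treatment_effect: -0.4
outcome_noise_sd: 0.0
outcome_basis: latent
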