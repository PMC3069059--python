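# Scenario 3: moderate non-additivity and non-linearity — ten two-way
# interactions and three quadratic terms on top of the scenario-1 main
# effects. Coefficients are scaled multiples (0.5 or 0.7) of the
# main-effect coefficients b1..b5; quadratics use b2, b4, b7.
scenario_id: 3
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
exposure_interaction_terms:
  - [1, 3, 0.4]     # 0.5 * b1
  - [2, 4, -0.175]  # 0.7 * b2
  - [3, 5, 0.3]     # 0.5 * b3
  - [4, 6, -0.28]   # 0.7 * b4
  - [5, 7, -0.4]    # 0.5 * b5
  - [1, 6, 0.4]     # 0.5 * b1
  - [2, 3, -0.175]  # 0.7 * b2
  - [3, 4, 0.3]     # 0.5 * b3
  - [4, 5, -0.2]    # 0.5 * b4
  - [5, 6, -0.4]    # 0.5 * b5
exposure_quadratic_terms:
  - [2, -0.25]      # b2
  - [4, -0.4]       # b4
  - [7, 0.7]        # b7
outcome_intercept: -3.85
outcome_coefs: [0.3, -0.36, -0.73, -0.2, 0.0, 0.0, 0.0, 0.71, -0.19, 0.26]
treatment_effect: -0.4
outcome_noise_sd: 0.0
outcome_basis: latent
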