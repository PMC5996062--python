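# Moderate-size synthetic study: `ohga run --config examples/study.yaml --out results/`
seed: 42
generator:
  n_subjects: 1500
  scenario: default      # default | proportional_odds | crosslag | null
missingness:
  mar_strength: 0.5
imputation:
  n_imputations: 5
  n_cycles: 2
mcmc:
  n_chains: 4
  n_warmup: 200
  n_draws: 400
  max_extensions: 2
po:
  n_quad: 11
var:
  n_quad: 7
n_pred_draws: 200
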