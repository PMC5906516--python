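# Full pipeline configuration for `eventnma run-all --config config.yaml`.
# Omit `generator` and set `data_path: <dir>` to analyse your own CSV tables
# (risk.csv / rate.csv / treatments.csv, schemas in eventnma.data).
seed: 7
out_dir: eventnma_run

generator:
  n_treatments: 8
  n_studies: 20
  format_mix: [12, 4, 4]      # studies reporting both / risk only / rate only
  true_log_hr: [0.0, -0.3, -0.2, -0.1, 0.05, 0.1, 0.2, 0.3]
  true_sigma: 0.3             # between-study SD, log-hazard scale
  baseline_lograte_mean: -0.9675840262617056   # log(0.38 events/person-year)
  n_range: [50, 500]

models:
  - {likelihood: binomial_logit,   effects: random}
  - {likelihood: binomial_cloglog, effects: random}
  - {likelihood: poisson_log,      effects: random}
  - {likelihood: shared,           effects: random}
  - {likelihood: shared,           effects: random, structure: inconsistency}

mcmc:
  chains: 4
  draws: 3000
  burn: 1000

economics:
  cost_per_event: 333.0       # GBP per severe hypoglycaemic event
  utility_decrement: -0.012   # per event-experiencer
  horizon: 1.0                # years
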