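# Small demonstration run: a 40-subject synthetic cohort, reduced model
# search and tuning budgets so the full pipeline completes in minutes.
seed: 7
output_dir: codevel_demo_out
log_level: INFO
simulate:
  n_subjects: 40
  k_states: 3
  n_taxa_nasal: 18
  n_taxa_rectal: 18
  n_immune_pops: 12
states:
  k_min: 1
  k_max: 5
  tol: 1.0e-5
scan:
  preset: adjusted
  max_vois: 12
dev_index:
  n_draws: 12
outcome:
  n_draws: 5
  eval_folds: 10
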