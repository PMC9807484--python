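# Run configuration for `mirameta all --config run_config.yaml`.
# `mirameta simulate --config run_config.yaml` first writes synthetic inputs
# to the paths below; point them at your own TSVs to analyse real data.
paths:
  corpus: inputs/corpus.tsv          # substudy table (documented 11-column TSV)
  ledgers:                           # interaction ledgers, any number
    - inputs/experimental_a.tsv
    - inputs/experimental_b.tsv
    - inputs/predicted.tsv
  retractions: inputs/retracted_pmids.txt   # one PMID per line
  pathways: inputs/pathways.tsv      # signed edge lists (pathway_id, name, src, dst, beta, relation)
  alias_table: null                  # null -> packaged alias TSV
  out_dir: run_out

meta:
  min_substudies: 2
  alpha: 0.05

subgroup_axes: [tissue, blood_fraction, platform]
sensitivity_thresholds: [25, 50]
bias_targets: auto                   # or an explicit list of microRNA names
top_pct: 1.4                         # prediction percentile cut (inclusive)
min_pmids: 2

impact:
  n_perm: 2000
  seed: 7                            # mandatory: drives every stochastic stage
  adjustment: bh                     # or bonferroni

selection:
  target_pathway_id: pw_planted
  alpha: 0.05
  apply_bias_gate_to_all: false

simulate:                            # only used by the `simulate` subcommand
  n_mirnas: 50
  n_studies: 40
  effect_mirnas: 5
  effect_logOR: 2.0
  tau_between: 0.3
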