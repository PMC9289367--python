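# One-command demo: simulate a 1,200-subject cohort, cluster, profile,
# compare, and tune the membership classifier.
#   rsbi-traj run --config examples/demo.yaml
outdir: out/demo
overwrite: true
seeds:
  simulate: 7
  cluster: 8
  predict: 9
simulate:
  n_subjects: 1200
cluster:
  n_init: 50
predict:
  n_explanations: 4
  compare_models: false
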