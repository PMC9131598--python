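# Full-pipeline configuration for `msatpop run --config examples/pipeline_config.yaml`.
# With `input: null` a study-shaped synthetic dataset is generated (and its
# truth ledger written next to the outputs); point `input` at a genepop file
# to analyse real data instead.
outdir: scratch/pipeline_demo
input: null
synth_scale: 0.25     # fraction of the published per-meadow sample sizes
mll_threshold: 2      # allele-difference threshold for MLL collapse
B: 2000               # permutations (>= 1320 so the 66-test level .000758 is reachable)
alpha: 0.05
drop: [CYP]           # excluded from the ABC pooling (small sample)
abc_rows_per_scenario: 1000
abc_retain_fraction: 0.02
abc_n_delta: 200
abc_use_mll_representatives: true
abc_sizes_scale: 0.5  # simulate at half the pooled sample sizes for speed
predictive_reps: 0
fca_axes: 3
seed: 1
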