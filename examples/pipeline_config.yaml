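# demo run configuration for `dentasym run examples/pipeline_config.yaml`
seed: 11
outdir: scratch/demo_run
n_individuals: 60
n_perm: 199
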