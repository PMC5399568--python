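# Two-group synthetic cohort: 15 control lobes (20% reporter-positive)
# vs 15 JAK-activation-like lobes (60%), reference imaging conditions.
seed: 1
output_dir: scratch/example_run
input:
  synthesis:
    groups:
      - label: control
        n_lobes: 15
        params:
          positive_fraction: 0.2
      - label: JAK
        n_lobes: 15
        params:
          positive_fraction: 0.6
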