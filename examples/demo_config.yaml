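# Demo pipeline config: run with
#   slc26kit report --config examples/demo_config.yaml
outdir: scratch/demo_run
seed: 1
stages: [residency, pore, variants]
residency:
  preset: preset_cl
  n_frames: 20000
  n_replicates: 3
  window: [3.5, 8.0]
pore:
  cleft_radius: 2.5
  threshold: 1.8
  occlusion: true
variants:
  source: curated
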