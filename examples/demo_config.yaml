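# Demo configuration for the end-to-end pipeline:
#   hepcyto run --config examples/demo_config.yaml --outdir runs/demo
assay: timelapse
seed: 0
n_fields: 1
band_um: 3.0
death_threshold_au: 100.0
segmentation:
  mode: smooth
simulation:
  field_width_px: 256
  field_height_px: 256
  n_frames: 13
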