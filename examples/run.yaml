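# Example run config for `ordvit train` / `ordvit ablate`.
# preset: tiny | base; `model` entries override preset fields.
preset: tiny
model: {}
train:
  lr: 0.001        # from-scratch rate for the tiny preset
  batch_size: 32
  max_epochs: 30
  patience: 5
  lambda_reg: 0.5
augment:
  p_hflip: 0.5
  p_vflip: 0.5
  rot_deg_max: 20.0
  translate_frac_max: 0.10
data:
  dir: example_data
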