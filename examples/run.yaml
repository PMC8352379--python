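# Full study-design run: 4 wavelengths × {GNR, saline} × 4 animals,
# simulated at the published group statistics (groups: null → defaults).
simulate: true
seed: 1
outdir: results
roi_diameter_px: 30
exposure_s: 90.0
span_floor_C: 1.0
weighted_fit: false
alpha: 0.05
groups: null
camera:
  frame_rate: 6.0
  width: 160
  height: 120
  noise_sd: 0.7
  quantization_step: 0.01
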