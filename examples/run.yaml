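# Demo pipeline run: two fields per grade-group preset, concordant panel.
outdir: runs/demo
seed: 7
n_nuclei: 80
microns_per_pixel: 0.5
presets:
  - {preset: group1, n_fields: 2}
  - {preset: group3, n_fields: 2}
  - {preset: group5, n_fields: 2}
segmentation:
  min_area_um2: 10.0
  border_policy: keep
concordant_panel: true
grading_alpha: 0.01
area_threshold_um2: 80.0
fraction_threshold: 0.10
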