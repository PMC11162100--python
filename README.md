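# uromorph

Quantitative nuclear-morphometry grading for urothelial carcinoma on
H&E-like field images.

Tumor grade in bladder cancer (low vs high grade urothelial carcinoma) is
decided from nuclear size, hyperchromasia and pleomorphism — features
pathologists assess by eye, with substantial inter-observer variability.
`uromorph` is a tested re-implementation of a morphometry-first grading
analysis for researchers in computational pathology: it segments every
nucleus in a 40x H&E field, measures 40 per-nucleus properties (geometry,
color intensity, texture, neighborhood), reduces them to per-image
summary statistics, calibrates linear grading functions against
pathologist score panels, and tests the association between grade and
tumor-infiltrating inflammation.  Because the analysis it follows
deposits no images or score tables, the package ships a synthetic-field
generator with full ground truth whose grade-group presets are calibrated
to the published group statistics, so the whole chain is exercisable and
falsifiable end to end.

## The model in brief

* **Per-image statistics.** For each feature x and image with nuclei
  x₁..xₙ, the summary keeps mean, SD, and the percentiles P₁₀ and P₉₀
  (linear interpolation at position (n−1)·q). The headline grade
  predictor is **P₁₀ of nuclear area**: high-grade tumors carry small
  infiltrating inflammatory nuclei (lymphocytes, neutrophils), which
  drag the 10th percentile *down* as grade goes up.
* **Grade groups.** From a five-pathologist panel (scores 1–5):
  group 1 = score 1 from ≥4 raters, group 5 = score 5 from ≥4 raters,
  group 3 = panel mean in [2.5, 3.5].
* **Selection and grading.** Each summary parameter is tested group 1 vs
  group 5 (Welch t-test, gate p < 0.01). A selected parameter grades an
  image by the two-point line through its group means,

  &nbsp;&nbsp;&nbsp;&nbsp;score(x) = 1 + 4·(x − m₁)/(m₅ − m₁), clipped to [1, 5],

  so score(m₁) = 1 and score(m₅) = 5 whatever the direction of the
  effect. Two gradings *agree* when |Δ| < 2 points.
* **Inflammation.** An image is inflamed when ≥10% of its nuclei are
  below 80 µm²; grade–inflammation association is tested with the
  closed-form 2×2 Pearson chi-square (Fisher exact as the zero-cell
  alternative).

## Worked example

```python
from uromorph import (PRESETS, CalibratedImage, calibrate_preset, render_field,
                      segment, extract_features, summarize, fit_linear_grader)

cfg = calibrate_preset(PRESETS["group5"])        # high-grade preset
rgb, truth = render_field(cfg, seed=1)
image = CalibratedImage(rgb, cfg.microns_per_pixel)
mask = segment(image)
feats = extract_features(image, mask, image_id="demo")
s = summarize(feats)
print(f"nuclei segmented: {mask.max()} (ground truth {len(truth.records)})")
print(f"mean area  {s['area_um2_mean']:8.1f} um^2")
print(f"p10 area   {s['area_um2_p10']:8.1f} um^2")
print(f"p90 area   {s['area_um2_p90']:8.1f} um^2")

grader = fit_linear_grader(m1=152.0, m5=52.0, feature="area_um2_p10")
print(f"predicted grade score: {float(grader.predict(s['area_um2_p10'])):.2f}")
```

Output:

```
nuclei segmented: 300 (ground truth 300)
mean area     614.1 um^2
p10 area       48.9 um^2
p90 area     1007.6 um^2
predicted grade score: 5.00
```

All 300 rendered nuclei are recovered; this single high-grade field's
statistics sit near the group-5 calibration targets (625 / 52 / 1050 µm²
for mean / P₁₀ / P₉₀ — single fields scatter around them), and the
two-point grader anchored at the group-1 and group-5 P₁₀ means (152 and
52 µm²) assigns the top grade because the image's P₁₀ is at the
high-grade anchor.

## Command line

```bash
uromorph generate --preset group5 --n-fields 5 --seed 7 --outdir fields/
uromorph segment fields/group5_f000.png --mpp 0.5 --out mask.png
uromorph features fields/group5_f000.png mask.png --mpp 0.5 --out nuclei.csv
uromorph aggregate nuclei.csv --out summaries.csv
uromorph run-all --config run.yaml --seed 7      # full pipeline + manifest
```

`run-all` executes generate → segment → features → aggregate → grade →
inflam, writes per-stage CSV/JSON artifacts and a manifest (seed, config
hash, per-stage counts, every file written), and reproduces byte-identical
tables when rerun with the same config and seed.

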