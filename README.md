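# collafluor

Objective, non-invasive assessment of collagen during wound healing, from
two measurement arms:

1. **Laser-induced autofluorescence spectroscopy.** Skin/granulation tissue
   excited at 325 nm emits with two major bands: collagen cross-links near
   405 nm and NADH near 455 nm, the NADH band being the global maximum.
   After Fourier smoothing, two-point baseline correction and normalization
   to the NADH peak, the collagen level of a spectrum is summarized by the
   normalized intensity at 405 nm, I(405), and the area under the curve
   over the collagen band, AUC(350–405 nm).
2. **Picro-Sirius red polarized-light histology.** Thick type I collagen
   fibers appear red/yellow birefringent, thin type III fibers weakly
   green. Each image pixel is converted to HSI (hue–saturation–intensity)
   space and scored against reference colors: score = max(0, 1 − d_hue/tol)
   with hard gates on saturation and intensity; percentage total collagen
   is the summed per-pixel score of red + yellow + green classes over the
   pixel count.

The package implements both arms plus the connecting statistics for a
three-group time-course design (un-wounded control, un-illuminated
control, laser-treated; days 0/5/10/30/45/60 post-wounding; the animal as
the statistical unit): mean ± SEM summaries, mixed repeated-measures ANOVA
with Bonferroni per-day contrasts, unpaired pooled t-tests for image
scores, and treated/control fold changes. A seeded synthetic-data module
generates spectra, full factorial studies and fiber images with known
ground truth, so the entire analysis is testable without animal data.

It is intended for researchers in tissue optics / wound-healing
photobiomodulation who want a reproducible, scriptable version of this
analysis rather than a chain of GUI tools.

## Spectrum files

Two-column delimited text (`wavelength_nm,intensity_au`) with a
`#`-prefixed metadata header (`animal_id`, `group`, `day`, `site`,
`replicate`, optionally `sex`, `age_weeks`). A study is a CSV manifest
with columns `file,animal_id,group,day,site,replicate`.

## Worked example

Simulate a full study (3 groups × 15 animals × 6 days × 4 sites × 4
replicates = 4320 spectra) under the bundled wound-healing trajectory
preset, then run the spectral pipeline:

```python
from collafluor import RunConfig, StudyDesign, run_spectral_pipeline
from collafluor.simulate import simulate_study

ds = simulate_study(StudyDesign(), seed=17)
tables = run_spectral_pipeline(RunConfig(out_dir="out"), dataset=ds)
print(tables["folds"].query("metric == 'intensity'").round(3))
print(tables["contrasts"].query("metric == 'intensity'")[["day", "p_adj", "label"]])
```

which prints (seed 17):

```
 day    metric  test_mean  control_mean  fold_change
   5 intensity      0.539         0.418        1.291
  10 intensity      0.576         0.448        1.286
  30 intensity      0.583         0.510        1.143
  45 intensity      0.547         0.544        1.005
  60 intensity      0.542         0.546        0.992

 day   p_adj   label
   5  0.0002 P<0.001
  10  0.0000 P<0.001
  30  0.0005 P<0.001
  45  1.0000      ns
  60  1.0000      ns
```

i.e. the treated group's collagen intensity exceeds the un-illuminated
control at days 5–30 (significant after Bonferroni adjustment over the six
days) and the two converge by days 45–60 — the qualitative signature of
accelerated early collagen deposition followed by remodeling.

The same entry points exist on the command line:

```bash
collafluor simulate study --seed 17 --out study/
collafluor spectra validate study/manifest.csv
collafluor metrics study/manifest.csv --out metrics.csv
collafluor simulate histo --seed 17 --out imgs/
collafluor histo score imgs/ --out scores.csv
collafluor run --config run.yaml
```

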