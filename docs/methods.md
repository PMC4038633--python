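# Methods

## Spectral model and preprocessing

An in vivo autofluorescence spectrum at 325 nm excitation is modeled as a
wavelength grid (native synthetic grid: 320–550 nm at 1 nm, 231 samples)
carrying two emission bands — collagen cross-links near 405 nm and NADH
near 455 nm — on a slowly varying baseline. The NADH band is the larger
of the two, so after preprocessing the global maximum is the NADH peak
and all intensities are expressed relative to it.

Preprocessing is a fixed three-stage chain, applied in this order:

1. **Fourier smoothing.** The intensities are FFT'd, the
   highest-frequency fraction *p* of rfft bins is zeroed (the study
   default is *p* = 0.80, i.e. the lowest 20% of bins are retained), and
   the signal is inverse-transformed. "Percent smoothing" conventions
   differ between spectroscopy packages (fraction of bins removed vs
   kept vs a kernel width); this package defines *p* as the removed
   fraction, documents it, and keeps the DC bin unconditionally so the
   spectral mean is never altered. A raised-cosine taper over the
   outermost 10% of retained bins suppresses truncation ringing.
   *p* = 0 is an exact identity.
2. **Two-point baseline correction.** The straight line through the
   intensities at two anchor wavelengths (default: the first and last
   grid points) is subtracted. Anchors read the single nearest grid
   point, no local averaging. Negative residuals are kept — clipping
   would bias the band integral upward.
3. **Normalization.** Intensities are divided by the global maximum (the
   raw maximum, not a fitted peak height). The wavelength of the maximum
   is recorded and a warning is attached when it falls outside the
   expected NADH window (default 440–470 nm) rather than silently
   assuming the normalization target; freshly wounded (day 0) tissue can
   deviate. A maximum ≤ 1e-12 raises an error: that is the numerical
   residue a degenerate (e.g. purely linear) spectrum leaves after
   baseline correction.

## Collagen metrics

* **I(405):** the normalized intensity at the grid point nearest 405 nm
  (ties to the lower wavelength). The wavelength is fixed, not searched;
  a per-spectrum peak search would change the statistic.
* **AUC(350–405):** composite-trapezoid integral, with linear
  interpolation at band edges that fall between grid points. On the unit
  plateau this is exactly 55 (the band width in nm), and against the
  closed-form Gaussian (erf) integral the 1-nm-grid trapezoid is accurate
  to ~0.001%.

Replicate structure follows the acquisition protocol: 4 spectra per site,
4 sites per animal per day. Averaging is two-stage with equal weights —
replicates within site, then site means within animal — so the animal is
the statistical unit entering group summaries (mean ± SEM with
n = animals, SEM = sd/√n). Wavelength grids must match exactly for
averaging; an explicit linear-interpolation resampler exists but is never
applied implicitly, because silent resampling can bias peak metrics.

Fold change is the treated/control ratio of group means at one day,
reported to 3 decimals for spectral metrics and 2 for image percentage
scores. Note one rounding artifact: the published day-45 total-collagen
means (15.88 / 11.06) give 1.436 → 1.44 at 2 decimals while the source
reports 1.43, presumably computed from unrounded means; comparisons
therefore carry a ±0.01 allowance at that point.

## Histology scoring

RGB pixels are converted with the classical arccos HSI formulation
(I = (R+G+B)/3 scaled to [0,1]; S = 1 − min/mean; H ← 360 − H when
B > G; achromatic pixels get H = 0, S = 0 and a false chromatic flag).
Against a reference color (hue center, hue tolerance, minimum saturation,
intensity range) a pixel scores max(0, 1 − d_hue/tol) with circular hue
distance, gated to zero outside the saturation/intensity admissibility
region. The published description of the scoring software gives the
qualitative contract — closer shades score higher, unrelated shades score
zero — but not the numeric scale; the linear-falloff [0, 1] score used
here is the minimal-parameter realization of that contract.

Per image, each pixel is assigned to the class (red / yellow / green)
with the highest positive score, ties broken red > yellow > green, so the
three classes are disjoint and total collagen (type I = red + yellow,
type III = green) never double-counts a pixel. Percentage score uses the
full pixel count as denominator (an all-reference image scores 100); the
original software's denominator is unpublished, and the ~15% values
reported for intact skin are consistent with this per-image
normalization. Default references (red 0° ± 20°, yellow 50° ± 20°, green
120° ± 30°, S ≥ 0.2, I in [0.05, 0.95]) are engineering defaults,
overridable in the YAML config; `ReferenceColor.from_rgb` anchors a
reference at the exact HSI hue of an RGB color, which is what makes the
scorer bit-exact against the pixel-counting oracle on synthetic images.

## Statistics

Spectral metrics: mixed two-factor ANOVA — group between subjects, day
within subjects (every animal measured at every day), no sphericity
correction — delegated to `pingouin.mixed_anova`, followed by per-day
treated-vs-control contrasts using the pooled-variance Student t-test
with a Bonferroni multiplier equal to the number of days tested.
Complete-case analysis: animals missing any day are dropped with a
warning. Image scores: unpaired two-tailed pooled t-test per day.
Significance labels use strict thresholds 0.05 / 0.01 / 0.001.
Degenerate inputs follow documented conventions: identical zero-variance
samples give t = 0, p = 1; zero variance with unequal means gives the
p → 0 limit with a warning; an all-constant ANOVA table returns F = 0.

The choice of day (not site) as the repeated factor, and of
treated-vs-un-illuminated as the contrast family, matches the per-day
significance letters used in time-course figures of this kind; the
original analysis does not state its ANOVA layout explicitly.

## Synthetic data

`simulate_spectrum` builds intensity = baseline + collagen Gaussian +
NADH Gaussian, multiplied by (1 − hemoglobin-dip Gaussian at 420 nm),
plus additive white Gaussian noise. Peak shapes are Gaussian by choice
(only plotted spectra are available, no lineshape data); the default
widths (collagen σ = 18 nm, NADH σ = 28 nm) were set so the un-wounded
preset lands near the reported normalized intensity of ~0.56 — a fixture
convenience, not a measured value. The hemoglobin dip defaults to off,
matching in vivo spectra where reabsorption is weak. Every generated
spectrum carries its ground truth: the noiseless spectrum's post-pipeline
normalized I(405).

`simulate_study` draws one collagen level per animal × day from a
group/day trajectory (normal, clipped to the model's realizable range
[0.22, 0.92] — the NADH tail alone contributes ~0.20 at 405 nm, setting a
floor) and solves the collagen amplitude by Brent root-finding on the
analytic (unsmoothed) normalized model so the noiseless value hits the
drawn target. The 16 replicates of an animal-day share that amplitude and
differ by additive noise (default sd 0.01 of the NADH amplitude) and a
small per-site baseline offset. The bundled `healing` preset encodes the
published group/day means with between-animal sds back-computed from the
printed SEMs (sd = SEM·√15); the two clearly corrupted printed SEMs
(day-0 values "±0.299" and "±0.1204") are both read as 0.0299, the
scale every neighboring value has. The preset is an emulation of the
reported curve shapes for testing, not a re-release of the data.

`simulate_histology` paints random thick line segments ("fibers") per
class onto a dark background, truncating the final stroke pixel-by-pixel
so the achieved class fraction equals the target to within one pixel, and
returns the exact achieved fractions. Class colors default to pure RGB
primaries/secondaries; optional Gaussian hue jitter (applied in HSV hue)
degrades scorer output monotonically, which is itself a tested property.

What the generators do **not** emulate: instrument response functions,
wavelength-dependent noise, scattering, photobleaching, hemoglobin
variation between days, stain variability, fiber texture/orientation
statistics, illumination gradients and white-balance error in microscopy.
Passing tests therefore demonstrate self-consistency of the pipeline
(parameter recovery, invariants, calibrated error rates) under the stated
generative model — not absolute spectroscopic or histometric accuracy on
real tissue.

## Problem sizes and numerical choices

The acceptance script runs 100 simulated full studies (4320 spectra each)
for the ordering-recovery rate, 10000 null replicates for t-test
calibration (Monte-Carlo sd ≈ 0.002), and 512×512 images for the scorer
oracle; the test suite uses the same designs with smaller replicate
counts where the check does not need the full size. Amplitude solving
uses Brent's method with xtol 1e-10 on a bracket (0, 0.999·NADH
amplitude]. Trapezoid integration and the FFT filter are exact to the
tolerances asserted in the tests (1e-9 for additivity and DC
preservation).

## Known limitations

* NADH normalization couples the collagen metric to metabolic state; if
  NADH levels change over healing, I(405) confounds the two. This is a
  property of the method being implemented, inherited deliberately.
* The "80% smoothing" convention of the original acquisition software is
  not public; this package's bin-fraction definition is a documented,
  reproducible stand-in, and conclusions that depend on the exact filter
  shape should be re-checked against the raw spectra.
* Hemoglobin-reabsorption correction near 420 nm is intentionally not
  performed (the generator can simulate the dip; the pipeline does not
  remove it).
* The histology scorer quantifies color closeness only; it does not
  segment fibers or measure thickness/orientation, and the qualitative
  scoring records are passed through for reporting without computation.
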