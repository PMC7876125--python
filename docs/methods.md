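# Methods

## The measurement model

`padsense` analyses a paper-based colorimetric assay whose detection zone —
a circular hydrophilic spot carrying a yellow Pt-complex receptor — fades
toward the paper background as the analyte (cyanide, µmol/L) concentration
increases.  The readout chain is:

1. **Zone averaging.**  Each photograph (reference, taken before analyte
   exposure; response, taken after) is reduced to the per-channel arithmetic
   mean (R, G, B) over the circular detection-zone ROI.  ROI membership uses
   the pixel-center-in-circle rule with no area weighting of boundary pixels;
   at the default radius of 20 px the boundary contributes well under 1% of
   the area, so the simplification is immaterial and keeps the mean exactly
   permutation-invariant and testable.
2. **Response statistic.**  ΔX = X_reference − X_response per channel, and the
   scalar "pure response" is the Euclidean norm ‖Δ‖ = √(ΔR² + ΔG² + ΔB²).
   The norm is insensitive to the sign convention; components are stored as
   reference − response.
3. **Calibration.**  Unweighted ordinary least squares of response on
   concentration over a stated linear range (default 1–100 µmol/L), with
   replicates entering as individual points.  Figures of merit:
   calibration sensitivity = slope (response units per µmol/L); Pearson r;
   LOD = 3·σ_blank/slope (the conventional 3σ criterion — σ_blank is the
   sample SD of blank-pair response norms); analytical sensitivity
   γ(c) = slope / replicate response SD at concentration c.
   Inverse prediction is c = (y − intercept)/slope, flagged (not truncated)
   when the estimate falls outside the linear range or below the LOD, so QC
   retains sub-LOD information.
4. **QC and comparison statistics.**  Replicate reproducibility as
   RSD = 100·SD/mean; shelf stability as the largest day through which every
   response stays within 5% (the assay's general tolerance) of the day-0
   response; optimization scans resolved by arg-max of the mean response with
   ties broken toward the smaller (resource-minimising) level; accuracy
   against a reference method via the per-sample relative error
   100·(sensor − reference)/reference and a pooled-variance two-sample
   Student t test on summary statistics with df = n₁ + n₂ − 2 (the Welch
   variant is available behind a flag but is not the default, because the
   method-comparison design reports df = 8 for n = 5 + 5, which forces the
   pooled form).  Interference tolerance limits: ratios of
   [foreign species]/[analyte] are scanned in ascending order and the
   tolerance is the largest ratio with |relative error| strictly below 5%
   before the first breach; if all tested ratios pass, the largest is
   reported with an `exceeds_max_tested` marker.

Reported concentrations and percentages are rounded to one decimal with ties
half-away-from-zero, the convention of analytical-chemistry tables.  Known
half-way inputs (e.g. 6.25%) are therefore reported as 6.3, and tests that
compare against externally reported tables document such cells as exclusions.

## The synthetic generator

No public image set exists for this kind of device, so every input is
simulated with stored ground truth (`padsense.synth`).  The generative color
model moves the zone's noise-free mean color linearly along the chord from
`receptor_color` (default (230, 200, 60)) to `paper_color`
(default (250, 250, 245)):

    zone_mean(c) = receptor + (m·c / ‖paper − receptor‖)·(paper − receptor)

which makes the extracted norm response exactly m·c — the simplest model
consistent with a linear calibration.  The default slope m = 0.8 response
units per µmol/L and linear range up to 100 µmol/L leave the c = 100 fade
(80 units) inside the 193-unit chord, so no channel clips.

Nuisance structure, chosen as the minimum that exercises the pipeline:

* **Pixel noise** — i.i.d. Gaussian per pixel per channel (default SD 2 on
  the 0–255 scale), then clipping to [0, 255].  Zone averaging over ~1250
  pixels suppresses this to ~0.06 intensity units on the mean.
* **Illumination** — a horizontal linear ramp spanning a fractional range
  (default 2%).  It cancels almost exactly in the reference/response
  difference for a centered zone.
* **Device scatter** — a multiplicative response factor ~ N(1, `device_rsd`)
  per fabricated device (default CV 3.77%, the reproducibility scale such
  devices exhibit), realised as an effective concentration.  This is the
  dominant replicate-to-replicate variance component; pixel noise alone
  cannot reproduce observed replicate RSDs because ROI averaging removes it.
* **Determinism** — every output is a pure function of its arguments
  including the seed; per-image streams are derived by stable hashing of
  (seed, operation, concentration, replicate), so datasets are reproducible
  bit for bit and subsets are independent.

In-memory images are float64 arrays in [0, 255]; writing PNG quantizes to
8 bits.  This keeps the noise-free linearity identity exact in memory (the
property tests rely on it) while the file interface stays standard 8-bit
sRGB.  Pipelines run on quantized files incur up to ±0.5 intensity units of
rounding per channel, visible in the CLI round-trip test as a <2 µmol/L
prediction tolerance.

What the generator does **not** emulate: camera optics and white balance,
JPEG artifacts, chemical kinetics, non-linear saturation at high
concentration, spatially correlated fabrication defects.  Passing tests
therefore demonstrate the correctness and statistical behaviour of the
*analysis*, not the physics of any real device.

### Calibrating blank noise to a stated LOD

For studies that state an LOD rather than raw blank responses,
`pixel_noise_for_blank_sd` inverts the noise model: a blank reference/response
pair differs only by averaged pixel noise, each channel difference has SD
σ·√(2/N_pix), and the norm of the trivariate Gaussian difference has SD
√(3 − 8/π) times that.  Requesting σ_blank = LOD·slope/3 yields the pixel
noise (≈4.0 for LOD 0.4 µmol/L at slope 0.8) that reproduces the stated
detection limit in expectation.

## Problem sizes and numerical choices

Default frames are 64×64 px with a radius-20 zone (~1250 ROI pixels): large
enough that boundary-pixel effects are sub-0.5% and averaging statistics are
in their asymptotic regime, small enough that a full calibration experiment
(6 concentrations × 5 replicates + 5 references + 20 blanks) simulates in
well under a second.  Multi-seed recovery studies use 20–50 seeds.

Degenerate inputs fail loudly rather than silently: zero concentration
variance, fewer than three distinct calibration concentrations, zero
replicate SD (undefined analytical sensitivity), both group SDs zero with
unequal means (infinite t), empty ratio maps, zones that leave the frame,
fades that overshoot the paper color.  Equality at the 5% interference
threshold fails (the criterion is strict inequality).  Optimum ties break
toward the smaller level deterministically.

## Known limitations

* The pooled t test consumes summary statistics; with raw determinations a
  paired design would be more powerful, but the comparison tables this
  package mirrors report only per-sample means and SDs.
* Auto-circle zone detection assumes a single zone darker/lighter than the
  border background by more than the color cutoff; multi-zone layouts and
  perspective distortion are out of scope.
* At the default 3.77% device scatter, the sample RSD of only five devices
  exceeds the 5% tolerance in roughly one run in seven — a property of the
  χ² sampling distribution of a 4-df SD estimate, worth remembering when
  interpreting single five-device reproducibility checks.
* The calibration is strictly linear; saturating (4PL) responses are not
  modelled, matching the assay's observed linear range.
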