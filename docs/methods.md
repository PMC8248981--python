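# Methods

This note documents the models implemented in `cdksize`, the conventions
and defaults chosen where the underlying experimental description leaves
the design open, and what the synthetic-data generator does and does not
emulate.

## 1. Generative model (`cdksize.synthetic`)

### Cell geometry and populations

Cells are rods: a cylinder of radius *r* (per ploidy; defaults 1.75 µm
haploid, 2.3 µm diploid) with hemispherical caps, total length *L*.
Volume is reported with the cylinder convention `V = π r² L` used
throughout the analysis. Lengths are drawn from a truncated normal
(default mean 10.5 µm, sd 2 µm, support [7, 16] µm); a uniform option
exists for designs that need equal occupancy of every size bin.

### C-CDK level

Two level models mirror the two experimental designs:

* `size_scaled` — steady-state scaling of concentration with size:
  `level = intercept + slope·L + ε`, slope in AU per µm of length
  (default 50 AU/µm, noise sd 25 AU). The slope is deliberately in length
  units: for a fixed radius, area or volume scaling would be collinear
  with length and add nothing.
* `induction` — size-independent induction sampled throughout the time
  course: a sampling time is drawn uniformly over the induction window
  (default 4000 s after a 1000 s lag) and
  `level = rate·(t − lag) + ε` (default rate 0.25 AU/s). This reproduces
  both the broad level range and the near-zero level–size correlation of
  sequential-sampling flow data.

### Activity response

Each genotype (WT, WT PP2AΔ, AF, AF PP2AΔ) carries an effective
half-activation level

    K_eff(L, ploidy) = K0 · exp(−c·(L − 10 µm)) + γ · DNA/V ,

where `c` is the size coupling (∂log K/∂L, negative direction: bigger
cells switch at lower C-CDK), and the additive term `γ·DNA/V`
(γ = 25 000 AU·fl by default, DNA units 1 per haploid genome copy)
implements titratable DNA-dependent inhibition — it vanishes at large
volume, so ploidies converge in big cells.

Given `K_eff`, the response is either

* **graded**: `a = bottom + (top − bottom)/(1 + (K_eff/level)^h)` plus
  Gaussian heterogeneity (sd 1.25 AU for the AF backgrounds — chosen to
  match the few-AU within-bin spread visible in graded single-cell
  violins), or
* **bistable**: the same curve evaluated as a switching probability
  `p_on`; the cell is "on" with probability `p_on` and its activity is
  drawn from `N(top, σ_sw)` or `N(bottom, σ_sw)` (σ_sw = 0.75). The mean
  curve of the bistable model equals the graded curve; bimodality and the
  sharper per-cell switch are what distinguish it.

This two-state emission is a simulator convention, not a mechanistic
claim: it is the minimal model that reproduces bimodal activity
distributions with a size-dependent switching threshold. Defaults:
WT K0 = 600 AU, h = 6, c = 0.25/µm, bistable; WT PP2AΔ identical but
K0 = 450 AU (PP2A loss shifts the threshold without reshaping the
response); AF K0 = 350 AU, h = 2.5, c = 0.10/µm, graded;
AF PP2AΔ K0 = 250 AU, h = 1.8, c = 0.05/µm, graded.

### Lineages

Per frame (default 3 min): length grows linearly (0.03 µm/min), level
accumulates in proportion to length (1 AU·µm⁻¹·min⁻¹, noise sd 10 AU),
and the division hazard is

    rate = baseline · logistic(size; x₀=9.5 µm, k=2/µm)
                    · logistic(level; x₀=450 AU, k=0.02/AU) ,

converted to a per-frame probability `1 − exp(−rate·Δt)`. The size and
level logistics carry separate sharpness parameters because a single
dimensionless value cannot serve both a µm-scale and an AU-scale axis.
At an event the level drops to a floor (20 AU, i.e. mitotic degradation);
with probability `1 − skip_division_prob` the length halves (division),
otherwise the cell keeps growing — degradation without division. The
default `skip_division_prob = 0.05` is the calibrated rate of that
phenotype in the AF background.

### Rendered images

A cell image holds two brightfield exposures and two fluorescence
channels (biosensor, level) at 0.15 µm/px. The fluorescence model:
uniform cytoplasm (100 AU) with a nuclear disc (radius = half the cell
radius) at `cytoplasm × N/C` in the biosensor channel; the level channel
is uniform at the true level inside the mask. Brightfield: a flat base
with (i) a deterministic dark cell-wall rim (depth 40 AU, width 1 px)
identical in both exposures — the shared cell outline — and (ii)
independent per-exposure texture inside the cell (sd 30 AU). Everything
is blurred with a Gaussian PSF (σ = 1 px) and given additive background
(10 AU) and read noise (sd 1.5 AU). Because the wall rim is shared it
cancels in the exposure difference, so segmentation sees only the
decorrelated texture; the rim is what a sub-pixel tip localiser can use,
exactly as in real brightfield.

The simulator does **not** model real optics (aberrations, shot noise,
z-stacks), crowded fields, cell-cycle-stage-dependent morphology, or any
mechanistic Wee1/Cdc25/PP2A network. Passing round-trip tests therefore
demonstrates internal consistency of the estimators under this noise
model, not performance on arbitrary real data.

## 2. Quantification (`cdksize.quantify`)

**Segmentation.** The per-pixel standard deviation of the brightfield
pair (|b₁−b₂|/2) is squared, Gaussian-smoothed (σ = 2 px), and
thresholded in two passes: a generous noise-floor cut (4× the global
median, which the background dominates) yields a provisional object, and
the final threshold is the midpoint between the interior and exterior
variance plateaus — the variance edge profile is symmetric about the true
boundary, so this midpoint localises the edge. Morphological closing
bridges speckle dropouts (thin cap cross-sections can fall below
threshold), holes are filled, and the largest component is kept. An empty
result raises a segmentation error and the cell is excluded downstream.

**Geometry.** The mask is rotated to horizontal by its principal axis.
Length uses sub-pixel localisation of the two cell-wall intensity minima
on the mean-brightfield midline (parabolic interpolation), falling back
to the half-maximum crossings of the smoothed stdev profile and finally
to the raw mask extent; the thresholded extent alone is speckle-limited
to ~1.5 px, which motivated the refinement. Radius is half the median
cross-sectional width of the central half of the rod (robust for rods,
unlike an ellipse fit); area is the mask pixel count; volume is the
cylinder formula.

**Level.** "Brightest group of 9 pixels" is read as the best contiguous
3×3 block: the maximum, over all 3×3 windows fully inside the mask, of
the window mean (sliding-window implementation; an alternative
`method="pixels"` takes the 9 brightest pixels anywhere in the mask).
Contiguity makes the estimator robust to isolated hot pixels, and a
block mean is a concentration — invariant to cell size.

**Activity.** The midline profile is the mean over a 3-px-wide band
(the middle row of the cell, widened by one pixel either side),
restricted to mask columns. The most prominent extremum — peak or dip —
is searched in the central 50% of the profile only, because the intensity
roll-off at the cell tips would otherwise dominate every prominence
computation. The cytoplasmic baseline is the mean of the two flanking
segments between 15% and 35% of the profile length from each end (tips
excluded to avoid cap roll-off). If no extremum exceeds 2× the robust
noise sd of the flanks, the cell is scored N/C = 1. Fluorescence channels
are background-subtracted (median outside the dilated mask) before both
estimators; without this the additive background would bias N/C toward 1.

**Focus and gating.** Focus is the RMS finite-difference gradient
magnitude scaled by a fixed factor (14.0) calibrated once so in-focus
synthetic renders score ≈ 70–80 and a 2-px blur drops far below the
conventional cut; gating keeps cells with focus **strictly above 65**,
then area and aspect ratio inside configurable single-cell windows.
Records are flagged, never dropped.

## 3. Dose–response fitting (`cdksize.dose_response`)

Both fitters are multi-start nonlinear least squares
(Levenberg–Marquardt) on log-scale shape parameters (log x₅₀, log |slope|)
with plateaus free (optionally pinned, e.g. top = 1 after DMSO
normalisation). Starts: the geometric mean of positive doses plus the
half-range crossing, × slope seeds {0.5, 1, 2, 4}; best RSS wins. The
Hill coefficient is reported signed, its sign taken from the data's
direction; the sigmoid slope is reported positive. Flat data (response
range below 2× a successive-difference noise estimate) return
`converged=False` rather than raising. Noiseless parameter recovery is
exact to optimiser precision; under 5%-of-top noise the EC50 bias stays
below 3% (tested over 200 replicates).

## 4. Division statistics (`cdksize.division`)

`estimate_pdiv` is the binned event-rate estimator: for every observed
cell-timepoint with a successor frame, the event indicator is a
degradation event at the next frame; per bin,
`rate = (events/timepoints)/Δt`. It is the plain binomial estimator —
no survival machinery — and is unbiased for the per-frame event
probability.

`threshold_level` groups each size bin into sliding level windows
(default 100 AU wide, 50% overlap, ≥ 20 cells per window), computes the
fraction with activity above the cut (default 5), smooths it with an
increasing isotonic fit (exceedance must be monotone in level up to
noise; the isotonic fit guarantees the unique crossing the analysis
assumes), and interpolates the first crossing of the target fraction
(default 50%). Bins that never reach the fraction, or with too few
cells, are flagged undefined with a reason code. The level-window scheme
is this package's choice; it is fully configurable.

`decompose_synergy` is exact algebra on four genotype curves sharing one
set of size bins; undefined thresholds are substituted by the cap
(default 1000 AU) *inside the algebra only*, and every bin touched by a
cap carries flags. With additive construction the recomposed curve equals
WT to machine precision; the residual (synergy) is positive when the
joint restriction exceeds the sum of its parts.

Note: the threshold is monotone **non-decreasing** in the target
fraction — requiring a larger fraction of cells above the cut cannot be
achieved at a lower level. (Tested as such.)

## 5. Bistability metrics (`cdksize.bistability`)

The mean activity-vs-level curve is the plain within-bin mean, which
averages the on/off subpopulations where the distribution is bimodal
(a two-component mixture readout is not provided in v1; with equal
subpopulation weights the plain mean coincides with the average of the
two component means). `max_gradient` fits a smoothing spline — smoothing
chosen by generalised cross-validation by default, or pinned via `lam`
for reproducibility — and returns the maximum first derivative over the
observed range, with a finite-difference fallback flagged on spline
failure. A `monotone` option applies an increasing isotonic fit first:
the raw max-of-derivative statistic is inflated by noise wiggles on
shallow curves, which biases cross-condition comparisons; the monotone
pre-fit removes that inflation. Gradients are taken on raw (not
normalised) activity.

`gradient_residuals` fits an ordinary least-squares line to max-gradient
vs length and scores nonlinearity as the lag-1 autocorrelation of the
length-ordered residuals: independent scatter around a genuine line
scores ≈ 0 (slightly negative in small samples), while a convex trend —
the signature of size-coupled bistable switching — leaves runs of
same-sign residuals and a positive score. The score is scale-free, so it
discriminates only while the flat condition's residuals remain
noise-dominated; the packaged contrast test therefore runs at
imaging-flow-cytometry sample sizes (~10⁶ cells per condition, matching
the experimental n of 10⁵–8×10⁵), uniform sizes over 7–16 µm, induction
levels reaching 2400 AU so that even the smallest cells' transitions are
within range, 0.4 µm size bins, and a monotone spline with lam = 10⁴.

## 6. Lineage analysis (`cdksize.lineage`)

Degradation events are frames where the level falls by ≥ 50% of the
running pre-drop maximum within 2 frames; divisions are frame-to-frame
size drops ≥ 30%. Both thresholds are this package's conventions (the
source description is qualitative — "steep decreases"), exposed as
parameters, and sit ≥ 5× above the generator's frame-to-frame noise;
both detectors are invariant to positive rescaling of their series.
A degradation with no division within ± 3 frames is classified
degradation-without-division; the population fraction carries a 95%
Wilson binomial CI. Alignment shifts each trace so the smoothed-activity
maximum (centred moving average, default 3 frames) sits at 0 min.
Mitotic entry is the first frame above `baseline + 3·robust sd` (baseline
from the first quartile of frames) from which the smoothed trace reaches
its peak without falling back below baseline — a documented stand-in:
the original automatic entry rule is not described, so no equivalence is
claimed.

## 7. Reproducibility

All randomness flows from one root seed: the pipeline derives a named
substream per stage (SHA-256 of the stage name folded into a
`SeedSequence`), and identical config + seed reproduces byte-identical
outputs, verified by content hashes in the pipeline manifest. Tables
round-trip through CSV/Parquet under a fixed schema (nullable activity,
boolean flags); images are multi-page TIFF (BF1, BF2, biosensor, level)
with pixel size in the image description.

## 8. Problem sizes used in the packaged checks

Parameter-recovery checks run on 7-dose / 25-level noiseless curves.
The quantification round trip renders 200 cells. The skipped-division
estimate uses ~2–12×10³ detected events. The threshold/synergy checks use
4–5×10³ cells per size bin; the bistability contrast uses 100 matched
replicate pairs of 1.3×10⁶ cells each. These sizes are chosen so each
statistic's Monte-Carlo error is small relative to the effect it
measures, while a full test run stays in the minutes range on a laptop.

## 9. Known limitations

* The wide-field (multi-cell, z-stacked) segmentation pipeline is not
  reproduced; quantification assumes one cell per image, as on an
  imaging flow cytometer, with the time-lapse variant reached by
  supplying pre-cropped cells.
* The simulator's bistable switch is phenomenological; no hysteresis
  (up/down ramps) exists in the data design, so none is tested.
* Gradient-RMS focus is instrument-specific; only the *ordering*
  (sharp > blurred, cut at 65) is preserved, not absolute comparability
  with any particular cytometer.
* `threshold_level` assumes exceedance is monotone in level; strongly
  non-monotone artefacts (e.g. quenching at very high expression) would
  be smoothed over by the isotonic fit rather than flagged.
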