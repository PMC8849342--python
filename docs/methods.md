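# Methods

This note documents the models, parameter defaults and numerical
conventions behind each analysis stage, the assumptions of the synthetic
generators, and the design choices made where the design was genuinely
open.

## Conventions used everywhere

* Arrays are `(channel, plane, y, x)`; the plane axis is depth (z, in µm,
  plane 0 nearest the surface) or time (t, in s, plane 0 earliest). Indices
  are 0-based.
* All standard deviations are population SDs (divide by N). At the pixel
  counts involved the distinction to the sample SD is immaterial, and the
  choice matches common image-statistics tools; tests use it consistently.
* "Brightest fraction" selection takes `ceil(fraction · N)` pixels; ties at
  the cut intensity are broken by raster order, making the selection
  deterministic.
* Median and mean filters are parameterised by a disk radius in pixels
  (radius 0 = identity). Binary erosion/dilation uses a 3×3 square
  (8-connected) element, the default of common imaging toolchains.
* Auto-thresholding offers Otsu, isodata (both via scikit-image) and
  Huang's fuzzy-entropy method (implemented here over a 256-bin histogram,
  since scikit-image does not provide it).
* Background ROIs are user-supplied, not auto-detected: choosing a dark
  region is an experimental judgement that an automatic detector would turn
  into an unvalidated assumption.

## Calibration

Pulse energy at the sample surface is `E = E_obj · exp(−α·d)` with `α` the
immersion-medium absorption coefficient (natural-log units per mm) at the
excitation wavelength and `d` the immersion path (mm). The coefficient is
instrument- and wavelength-specific and therefore configuration (a YAML
table), never a built-in constant; the single Beer–Lambert factor is the
module's declared model. Average power is pulse energy × repetition rate
(nJ × MHz = mW). Depth-dependent energy schedules are piecewise-linear in
depth, exact at their grid nodes, and refuse to extrapolate.

## Excitation-order fitting

The order `n` of a multiphoton process is estimated from frames at
stepwise-varied pulse energy `P`, each followed by a reference frame at a
fixed low energy. Per frame,

    S(P) = F · [I_mean(P) − B_mean(P)] / [I_ref − B_ref]

where the denominator uses the reference frame *paired with* that
measurement (acquired immediately after it), so any mono-exponential
bleaching cancels up to a constant factor that does not affect `n`. `F`
defaults to normalising max(S) = 1; the constant is immaterial to the
exponent.

`S(P) = A·Pⁿ` is fitted by orthogonal distance regression (scipy.odr),
initialised from a log-log ordinary least-squares fit. Signal errors are
propagated in quadrature from the standard errors of the numerator and
denominator means (σ/√area); energy errors default to a 3% relative
uncertainty — the attenuator-calibration inaccuracy is not otherwise
quantified, so this is an explicit configuration value reported with the
fit, not a measurement. An axis whose stated errors are all zero is left
unweighted (the reduced χ² is then not a calibrated statistic and the QC
gate is meaningful only with realistic errors). Saturation and damage
limits are excluded through an explicit user-chosen fit range, not
auto-detected. Quality gates: reduced χ² < 2 and adjusted R² > 0.995,
enforced strictly.

## SNR and depth limit

Per depth, `SNR = (I_mean − B_mean)/σ_B`: `I_mean` over the brightest
fraction of the median-filtered plane (typical fractions: 1% for harmonic
signals with median radius 1; 10% nuclear and 40% cytosolic labels with
radius 2), background statistics over a dark ROI of the *unfiltered*
stack. Whether σ_B is per-plane or pooled over the stack is a config
switch (`per_plane_background`, default per-plane); both modes are
provided because either is defensible and the choice should be recorded
with the run.

The depth limit is where the piecewise-linear interpolant of (depth, SNR)
last falls below the threshold (default 3): the reported depth is the
deepest point at which the interpolated SNR still equals the threshold.
This makes the limit monotone non-increasing in the threshold and
first-order independent of the depth grid. A profile still above threshold
at the deepest plane returns that depth flagged "not limited"; one that
never reaches threshold returns no depth.

## Axial resolution

Per feature ROI, the ROI-mean z-profile is min-max normalised to [0, 1]
and differentiated with central differences (one-sided at the profile
ends, via `np.gradient`); the score is the maximum absolute slope in
µm⁻¹. Flat profiles are excluded with a warning. The summary is the
median and SD over features; counts outside the 11–17 band warn, since
smaller sets give unstable medians. Note that with central differences an
isolated mid-profile unit step over step h scores 1/(2h); only a step at
the profile end scores 1/h.

## Attenuation length

`S(z) = N·[(I_mean − B_mean)/Pⁿ]^(1/n)` removes both the excitation ramp
and the process order from the depth profile, so in homogeneous tissue
`S(z) = A·exp(−z/l_e)`: the effective attenuation length is the depth over
which ballistic excitation falls by 1/e, hence an order-3 signal by 1/e³.
Fitting S with a single exponential is algebraically identical to fitting
`(I−B)/P³` with `A·exp(−3z/l_e)` (a property covered by test). `N`
defaults to scaling the first valid point to 1. Depths with
`I_mean ≤ B_mean` are masked with a warning. Layered tissue is fitted with
per-layer windows, chosen explicitly by the user (layer boundaries are an
anatomical judgement). For order-2 profiles the same formulas apply with
n = 2; this generalisation is provided but flagged as an extension in
reports.

## Photobleaching

Per scan: mean filter (disk radius 2) → average z-projection (identity for
already-projected time lapses) → auto-threshold (Huang or isodata,
channel-dependent) within the cell ROI → mean of selected pixels → minus
the mean over a user-designated dark region. Decline after scan k is
`100·(1 − S_k/S_0)`; the series is invariant to global intensity scaling.

## Phototoxicity

**Traces.** Intensity-time traces are sampled as the mean over a 2-px
disk at tracked coordinates. (Whether "2-pixel mean" denotes a radius or a
kernel width is ambiguous in common toolchains; radius is this package's
documented choice, and it is configurable.) Display-scaling factors
applied by acquisition software are omitted: every downstream statistic is
scale-invariant. The Sytox trace is `(nucleus − bg)/(cytosol − bg)`, which
cancels the GCaMP crosstalk shared by both compartments. Smoothing is
Savitzky–Golay, window 10 points, order 2 (note scipy evaluates even
windows at a half-sample offset; exact polynomial reproduction at sample
points requires an odd window), with normalisation to the maximum of the
identically processed cytosol trace.

**Responder call.** Threshold = mean + 3·SD of the *unsmoothed*
pre-exposure baseline; a cell is responsive if the trace crosses it after
the baseline. Under a Gaussian null with known parameters the per-sample
exceedance is the one-tailed 3σ level (~0.00135, i.e. p ≈ 0.0015); with
the threshold *estimated* from a 50-frame baseline the exact null
exceedance is larger (~0.0025, computable by integrating the normal
survival function over the sampling distribution of the baseline mean and
SD — the test suite checks the measured frequency against exactly that
value). Checking crossings on the smoothed trace (threshold still from the
unsmoothed baseline) suppresses single-frame noise excursions and is what
makes the per-cell call specific over long recordings; `classify_responder`
takes the smoothed trace as an optional second argument for this purpose.

**Area analysis.** Threshold `t = mean + 3·SD` over the 95% dimmest ROI
pixels (pixels at or below the 95th percentile, ties included) of the last
pre-exposure frame. Per frame, the positive mask is `median(radius 1) > t`
inside the ROI. Pixels already positive before exposure (last pre-exposure
frame for time lapses; union of all pre-exposure planes for z-stacks) are
dilated 6 steps to absorb drift/expansion and subtracted from each frame's
mask. The responding fraction divides by the ROI area corrected for the
*undilated* pre-exposure positive area: this matches the definition of the
correction (pixels positive prior to exposure) and makes the fraction
non-increasing in the dilation margin, which dividing by the dilated area
would violate. The exposure summary is the maximum fraction during the
exposure window; groups are compared with the two-sided Mann–Whitney test
plus median/quartile summaries.

## Synthetic generators

The generators produce the statistical structure the estimators assume —
no optics are simulated (no wave propagation, aberrations or scattering
phase functions), and focal-volume differences between process orders
enter only through the exponent `n` and the PSF widths.

* **Depth stacks.** Expected plane at depth z: background (10 counts) +
  Gaussian blob features scaled by `(P(z)/P(0))ⁿ · exp(−n·τ(z))`, with
  `τ` the (optionally layered) optical thickness `∫dz/l_e`. The default
  schedule ramps surface energy exponentially 4.6 → 32 nJ across the
  stack, the compensation typical of deep imaging; the default feature
  amplitude (240 counts) puts the surface SNR near 50, the condition under
  which recovery is tested. PSF defaults (0.35 µm lateral, 1.3 µm axial
  Gaussian σ) correspond to sub-µm lateral / ~3 µm axial resolution.
  Axially confined features carry a Gaussian axial profile, which is what
  the resolution scorer measures.
* **Noise.** Shot noise is Poisson below 20 expected counts and its
  variance-equal-mean Gaussian approximation above (indistinguishable
  there, much faster); read noise is additive Gaussian (default SD 2);
  output clipped at 0.
* **Power series.** Alternating measurement/reference scans; each scan
  removes a `bleach_rate` fraction of fluorophore, so frame k sees
  residual `(1−r)^(2k)` and its reference `(1−r)^(2k+1)` — the protocol
  the bleaching correction is designed for. An optional multiplicative
  `rel_noise` models per-frame excitation fluctuation.
* **Viability movies.** Static cells (nucleus disk r = 2 px inside a
  cytosol shell to r = 7 px, geometry chosen so a 2-px sampling disk at
  the track points stays within one compartment). The baseline Ca²⁺
  fluctuation is a stationary AR(1) with frame-to-frame correlation 0.4
  and SD 4 counts on a ~100-count baseline — calcium dynamics are slow
  relative to the 2 s frame time, so white-noise baselines would be
  unphysical. Populations: quiet (0.55), spontaneous transients (0.20),
  steep responders (0.15, rise time constant 0.5 frames: stress-induced
  Ca²⁺ elevation is near-instantaneous with exposure onset) and gradual
  responders (0.10, linear ramp over the exposure). Response amplitude
  defaults to 5× the baseline SD — clearly above the 3σ call threshold.
  Dying (steep) cells additionally take up the nuclear dye after a
  normally distributed delay (mean 20, SD 5 frames) with a saturating
  exponential (τ = 6 frames) that starts exactly at the onset frame. The
  red nuclear channel optionally bleaches mono-exponentially during
  exposure.

What passing tests on this data do **not** show about real recordings:
cell motion and tissue drift (only a global dilation margin is exercised),
non-Gaussian baseline artefacts, depth-dependent background (the
generator's background is flat), spectral crosstalk beyond the single
nucleus/cytosol factor, and detector nonlinearity.

## Problem sizes

Recovery statistics in the test-suite run at the conditions above: 200
seeded replicates per order for the power-law fits, 100 per attenuation
length at surface SNR 50, 1000 traces for the null calibration, and one
200-cell movie for sensitivity/specificity. The acceptance script uses the
same conditions with 50/30 replicates per section, which keeps its full
run under a minute while the medians remain stable.

## Known limitations

* The reduced-χ² QC gate presumes realistic per-point errors; with
  degenerate (all-zero) stated errors the fit falls back to unweighted
  regression and the gate loses its calibration.
* The Huang threshold is histogram-based (256 bins); images whose dynamic
  range is dominated by a few hot pixels may need pre-clipping.
* The depth-limit interpolation is linear in (z, SNR); strongly curved
  profiles sampled coarsely will bias the crossing slightly.
* Responder classification assumes a stationary baseline; slow drifts
  inflate the baseline SD and desensitise the call rather than producing
  false positives.
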