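# Methods

This note documents the models implemented in `grousevis`, the defaults
they ship with, the numerical choices behind them, and what the synthetic
data generators do and do not emulate.

## Visual-pigment template and λ_max fitting

Pigment absorbance is modelled with the standard A1 (11-cis-retinal)
template.  The α-band is a function of `x = λ_max/λ`:

```
S(x) = 1 / (exp[A(a−x)] + exp[B(b−x)] + exp[C(c−x)] + D)
A = 69.7, B = 28, C = −14.9, D = 0.674, b = 0.922, c = 1.104
a = 0.8795 + 0.0459·exp(−(λ_max−300)²/11940)
```

The optional β-band is a Gaussian with peak `189 + 0.315·λ_max`, width
`−40.5 + 0.195·λ_max` and amplitude 0.26.  The β-band is **on** by default
for fitting and perception-range work, since near-UV shoulder absorbance is
physiologically real for violet-sensitive pigments; it can be disabled per
call.  Curves are evaluated on a 0.1 nm grid (300–800 nm) for peak and
cut-off location; cut-offs are linearly interpolated between bracketing
grid points and rounded to 1 nm only in reports.  Ties in a gridded argmax
resolve to the lowest wavelength, for determinism.

λ_max is estimated by least squares against the template: a 1 nm coarse
search over 330–620 nm followed by bounded scalar refinement to 0.01 nm.
When no fit window is supplied, a full-range pilot fit sets the window to
[λ̂−60, λ̂+100] nm, which avoids β-band and instrument-edge contamination
on the short side while keeping the information-rich long limb.

**Amplitude handling.** Spectra are peak-normalised before fitting, but the
template amplitude is co-estimated analytically (ordinary least squares
scale per candidate λ_max) rather than pinned at 1.  Pinning the amplitude
couples the fit to the single noisiest grid point — the observed maximum —
which biases λ̂ low by ~0.1–0.2 nm at realistic noise levels and, because
the bias repeats in every bootstrap draw, collapses confidence-interval
coverage (≈40% observed instead of 95%).  With the free scale the estimator
is unbiased and coverage is ≈93–95% in seeded simulations.
`free_amplitude=False` restores the pinned variant.

**Bootstrap.** With n ≥ 2 replicate spectra the aliquot replicate is the
exchangeable unit: each of the (default 1000) bootstrap draws resamples
replicates with replacement, averages them, and refits; with n = 1 a
residual bootstrap is used.  The point estimate is always the fit of the
plain replicate mean, the interval the 2.5/97.5 percentiles of the
bootstrap estimates, and the fit window is pinned once from the mean fit so
every draw optimises the same objective.  Everything is driven by a single
integer seed and is bit-reproducible.

## Oil droplets and effective cone sensitivity

C-, Y- and R-type droplets are long-pass cut-on filters modelled as
logistic curves in wavelength, `T(λ) = 1/(1+exp(−k(λ−λ_mid)))`, with 50%
transmission at λ_mid.  Defaults: C-type λ_mid from the empirical galliform
relation `0.82·λ_max,SWS2 + 75` with k = 0.15 nm⁻¹; Y-type 523 nm and
R-type 586 nm with k = 0.12 nm⁻¹; T-type droplets transmit fully.  The
logistic is one defensible reading of a "0.2 log-unit per 10 nm" cut-on
steepness; the slope parameter k is what the code exposes, and the
functional form sits behind a single function so a ramp variant can be
swapped in.

Effective cone sensitivity is the pointwise product of the peak-normalised
pigment absorbance and the droplet transmission.  The stored spectrum is
renormalised to peak 1 for plotting and comparison.  The 5% cut-offs,
however, are located on the *attenuated* product — the level is referenced
to the unfiltered pigment's peak.  This matters on the long limb: a cut-on
filter transmits almost fully there, so the attenuated product inherits the
pigment's descending limb and its 5% crossing (LW: 644.5 nm on the 0.1 nm
grid), whereas renormalising first would artificially push the crossing to
658.7 nm.  Lateral filtering cannot extend sensitivity beyond the pigment's
own exponential decay, so the pigment-referenced convention is the
physically meaningful one.

The whole-eye perception range takes its lower bound from the SWS1
pigment's short-limb 5% crossing (SWS1 cones carry transparent T-type
droplets) and its upper bound from the LW pigment's long-limb crossing.
With the β-band included the short limb never falls to 5% inside the
300–800 nm grid (the β-band holds ~27% absorbance at the grid edge); the
grid's lower edge is then reported as the uncrossed bound.  A measured
lower limit additionally reflects ocular-media (cornea/lens) UV filtering,
which is explicitly not modelled here.

## Contrast sensitivity function

A trial is one presentation of a drifting sinusoidal grating at a given
spatial frequency (cpd) and Michelson contrast `(I_max−I_min)/(I_max+I_min)`;
the response is the presence of the optocollic reflex.  Each frequency ×
contrast combination is presented five times and judged reliable when at
least four presentations elicit the reflex.  The threshold contrast at a
frequency is the lowest reliable level; sensitivity is its exact inverse.

The high cut-off frequency (sensitivity 1, i.e. only a full-contrast
grating is detectable) is found on the descending high-frequency limb by
log–log linear interpolation, or extrapolation of the two highest
measured points when all sensitivities exceed 1 — which is the normal case,
since the maximum presentable contrast of 0.99 bounds measured
sensitivities below 1.01.  A curve whose peak sensitivity is below 1, or
with no descending limb, has no cut-off.

Group summaries average per-individual peak frequencies and peak
sensitivities arithmetically, and average sensitivities (not thresholds) at
shared frequencies for the mean curve.  Printed report values use
half-down rounding to two decimals (so a mean optimal frequency of
0.955 cpd prints as 0.95, matching convention for truncated reporting),
with exact values retained in the returned summary.

The default contrast ladder is 12 log-spaced levels spanning the tested
0.012–0.99 range; ladders are fully configurable, and the pipeline's
default scenario uses an explicit stepwise ladder
(0.012, 0.02, 0.03, 0.06, 0.1, 0.15, 0.25, 0.4, 0.6, 0.8, 0.9, 0.99) whose
0.06 rung makes the canonical peak sensitivity 1/0.06 = 16.67 reachable.

## Detection geometry

The acuity chain is anchored to the measured species pair: axial length
`AL = 1.66·CD` (the diurnal-eye proportionality, 13.28 mm at CD 8.00 mm)
and spatial resolution `SR = 9.81·(AL/13.28)^γ` cpd.  The default exponent
γ = 1 encodes acuity proportional to posterior nodal distance at conserved
photoreceptor pitch; the exponent is a parameter for users who prefer a
steeper interspecific allometry.  Both functions carry their anchor values
in tests so any transcription drift is caught.

Detection distance is `D = v·t_react` (defaults 16.04 m s⁻¹, the
body-mass-predicted flight speed, and 2 s).  Marker spacing within the
binocular field is `d = 2·D·tan(θ/2)` with θ the binocular overlap
(28° → ≈16 m at D = 32 m).  The minimum resolvable object width is
`w = D·tan(1/(2·SR)°)`: one cycle at the acuity limit spans two bars, hence
the factor 2 in the angular term.  Acuity degrades roughly 5-fold in dull
light, so the low-light width is 5·w (142.7 mm at the defaults; 142.5 mm if
the rounded 28.5 mm is scaled instead — reports round D and d to the metre
and w to 0.1 mm).  Mass-to-speed conversion is deliberately not included:
speed is an input.

## Visual fields

Azimuths are margins relative to the median sagittal plane, measured per
eye with the eyes converged (forward) or diverged (backward).  The
binocular width at an elevation is the sum of the two converged margins
(clipped at zero); the blind sector behind the head is the sum of the two
diverged margins; each eye's lateral field is its monocular extent
(converged margin + 180° − diverged margin) minus the binocular sector.
These definitions make cyclopean = binocular + 2·lateral and
cyclopean + blind = 360° exact identities.

Because the perimeter arm sits at finite radius R while each eye is offset
e/2 from the head's median plane, raw azimuths are corrected to an infinite
viewing point by planar geometry per elevation: the corrected azimuth is
the direction of the ray from the eye to the perimeter point,
`atan2(R·sinφ − e/2, R·cosφ)`.  The correction is the identity as e → 0 or
R → ∞, and its inverse (ray–circle intersection) round-trips to 10⁻⁶ deg.
Elevations blocked by the bill holder are interpolated as the mean of the
widths immediately above and below, and flagged in the output.

## Marker contrast analysis

Each marker material's reflectance spectrum (300–780 nm, 1 nm, percent;
values above 100% from fluorescent elements pass through untouched) is
reduced to its arithmetic mean — no illuminant or receptor weighting, by
design.  Pairwise Michelson contrasts use an absolute-value numerator so
the matrix is symmetric and in [0, 1] regardless of material order.  A pair
is detectable when `1/C_m ≤ 16.67` (the species' peak contrast
sensitivity), boundary inclusive; zero contrast is undetectable by
definition.  Diffuse and diffuse-plus-specular components are analysed
separately and never mixed in one matrix; single-material markers are
excluded as having no internal contrast.

## Synthetic data

The generators reproduce the statistical structure each stage assumes, not
instrument physics:

- absorbance replicates = template + independent Gaussian noise per grid
  point (default sd 0.02 on a unit-peak curve, n = 7/6/3/7 replicates per
  pigment in the default scenario), with optional per-replicate baseline
  offsets;
- OCR trials from a deterministic observer (responds iff true sensitivity ≥
  1/contrast) with an independent lapse probability, five presentations per
  combination, and pseudorandom directions never repeating more than three
  times;
- reflectance profiles as baseline + Gaussian bumps, optionally noisy and
  clipped at zero;
- perimeter boundaries realising a given true field map, with optional
  Gaussian angular noise and dropped (blocked) elevations.

Real spectrophotometer data additionally show stray light, detector
changeover steps and wavelength-correlated noise; real observers drift in
attention; real perimeter readings share systematic head-alignment error
between eyes.  Passing the synthetic recovery tests therefore demonstrates
the pipeline's correctness, identifiability and seeding, not robustness to
every instrument artefact.

Simulation sizes used in the test suite (e.g. 60 coverage repetitions at
120 bootstrap draws, 200-draw bootstraps in the default pipeline scenario)
were chosen to estimate the relevant proportions to a few percent while
keeping a full run comfortably desk-scale; the statistical conclusions are
unchanged at 1000 draws.

## Known limitations

- No A2 chromophore templates, rod pigments, double cones, or ocular-media
  transmission; no receptor-noise chromatic discrimination modelling.
- The perception range's lower bound is template-referenced and does not
  model corneal UV filtering (see above).
- The acuity and eye-size relations are anchored single-species
  calibrations, not refitted regressions.
- CSF cut-offs beyond the measured frequency range are extrapolations and
  inherit the usual risks of extrapolating a two-point log-log slope.
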