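# grousevis

Modelling toolkit for the visual system of the black grouse (*Lyrurus
tetrix*) — and, more generally, for quantifying how a bird's vision limits
its ability to detect aerial obstacles and the visual markers meant to
prevent collisions with cables and ski-lift infrastructure.

The package implements the full analysis chain for this kind of sensory-
ecology study:

- **Visual pigments** — estimate the wavelength of maximal absorbance
  (λ_max) of each cone opsin (SWS1, SWS2, Rh2, LW) by least-squares fitting
  of the standard A1 pigment template
  `S(x) = 1/(e^{A(a−x)} + e^{B(b−x)} + e^{C(c−x)} + D)` with `x = λ_max/λ`
  (optional β-band shoulder), with bootstrap 95% confidence intervals over
  replicate absorbance spectra.
- **Cone sensitivities** — model oil-droplet filtering as a logistic cut-on
  `T(λ) = 1/(1+e^{−k(λ−λ_mid)})` (C-type `λ_mid = 0.82·λ_max,SWS2 + 75`;
  Y 523 nm, R 586 nm; k = 0.15/0.12 per nm) and compute effective
  sensitivities as pigment absorbance × droplet transmission, with peak and
  5% cut-off wavelengths.
- **Contrast sensitivity** — turn optocollic-reflex (OCR) trial tables into
  threshold contrasts per spatial frequency using the four-of-five
  reliability rule, and summarise the contrast sensitivity function (peak
  sensitivity `1/C_m`, optimal frequency, high cut-off frequency where
  sensitivity falls to 1).
- **Detection geometry** — the eye-size acuity chain (corneal diameter →
  axial length → spatial resolution in cycles per degree) and the
  collision-relevant distances: detection distance `D = v·t_react`, marker
  spacing `d = 2·D·tan(θ/2)` within the binocular overlap θ, and minimum
  resolvable object width `w = D·tan(1/(2·SR)°)`, scaled 5× under degraded
  light.
- **Visual fields** — perimeter boundary measurements corrected to an
  infinite viewing point, blocked-elevation interpolation, and the
  horizontal decomposition into binocular / lateral / blind sectors.
- **Marker contrasts** — mean reflectance (300–780 nm) per marker material,
  pairwise Michelson contrasts `C_m = |R₁−R₂|/(R₁+R₂)`, and detectability
  against the species' peak contrast sensitivity (`1/C_m ≤ 16.67`).
- **Synthetic data** — seeded generators for every input kind, so the whole
  pipeline runs end to end with no external downloads.

## Worked example

```python
import grousevis as gv

# eye-size acuity chain and collision geometry
report = gv.geometry_report(corneal_diameter_mm=8.00,
                            flight=gv.FlightParams(16.04, 2.0, 28.0))
print(report["axial_length_mm"])            # 13.28
print(report["spatial_resolution_cpd"])     # 9.81
print(report["detection_distance_m_report"])  # 32
print(report["marker_spacing_m_report"])      # 16
print(report["min_object_width_mm_report"])   # 28.5

# droplet-filtered cone peaks
droplets = gv.default_droplets()
for cone in ("SWS2", "Rh2", "LW"):
    ecs = gv.effective_sensitivity(gv.BLACK_GROUSE_LAMBDA_MAX[cone],
                                   droplets[cone], cone_name=cone)
    print(cone, round(ecs.peak_nm), round(ecs.upper_cutoff_nm))
# SWS2 449 511 / Rh2 530 569 / LW 595 644
```

A grouse flying at 16.04 m s⁻¹ with a 2 s reaction time must detect an
obstacle 32 m ahead; with 9.81 cpd acuity the obstacle must be at least
28.5 mm wide (142.5 mm on a dull day), and adjacent markers at most ~16 m
apart to stay within the 28° binocular field.  The long-wave cone's 5%
cut-off near 644 nm bounds achromatic perception of red materials.

The same analyses are available from the shell:

```
grousevis run-all --out results --seed 1
grousevis geometry
grousevis simulate --out inputs     # synthetic CSV inputs for every stage
```

`run-all` fits pigments on synthetic replicate spectra, models cone
sensitivities, recovers CSFs from simulated OCR trials, computes the
geometry chain, builds the visual-field map and the marker contrast
matrices, and writes a single `report.json` plus per-stage CSVs.

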