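# Methods

`nirskin` models how skin blood-flow fluctuations interfere with
near-infrared non-invasive glucose measurement, and quantifies the gain
from stabilising blood flow before an oral glucose tolerance test (OGTT).
This note records the models, the synthetic study conditions, the
numerical choices, and the limits of what the tests demonstrate.

## Skin optical model

The tissue is a seven-layer slab stack under a glass probe window
(n = 1.4, 0.2 mm): stratum corneum, living epidermis, papillary dermis,
upper blood net dermis, reticular dermis, deep blood net dermis and
subcutaneous tissue, with thicknesses 0.002/0.008/0.02/0.01/0.16/0.012/
0.65 cm.  Each layer carries volume fractions of blood (C_B), interstitial
water (C_H2O) and remaining components (C_Other = 1 − C_B − C_H2O):
C_B = 0/0/4/30/4/10/5 % and C_H2O = 5/20/50/60/70/70/70 % from top to
bottom.

Absorption per layer:

- stratum corneum: μa(λ) = 0.1 − 8.3·10⁻⁴·λ[µm] + 0.125·μa,Other(λ).
  With the wavelength in nanometres the linear term would exceed the
  constant term a thousandfold and make μa negative across the whole
  1000–1700 nm band, so the implementation evaluates it in micrometres
  (≈0.099 cm⁻¹ baseline); the coefficient is a configuration argument and
  a floor-at-zero with a warning guards any convention.
- living epidermis: μa(λ) = 0.5·10¹⁰·λ⁻³·³³·(1−C_H2O) + C_H2O·μa,H2O(λ),
  with λ in nanometres (this yields the expected ≈0.5 cm⁻¹ at 1000 nm).
- dermal and subcutaneous layers: the volume-fraction mixture
  μa = C_B·μa,B + C_H2O·μa,H2O + C_Other·μa,Other.

Reduced scattering μs′ is tabulated per layer on the wavelength grid and
converted for transport through the similarity relation μs = μs′/(1−g).
Anisotropy g = 0.9 and tissue refractive index n = 1.37 are standard
skin-optics defaults (the layer table does not specify them) and are
configurable per layer.

### Blood-volume perturbation

Vasodilation or drainage changes C_B only in the two blood-net dermal
layers; all other layers and the interstitial water content stay fixed.
A relative change r = ΔC_B/C_B (the canonical setting is +50 %) acts on
both coefficients:

- absorption: Δμa = ΔC_B·μa,B + k·ΔC_B·μa,Other with ΔC_Other = k·ΔC_B and
  k = −1 (the displaced volume trades against the "other" components).
  Δμa here consumes the *absolute* change ΔC_B = r·C_B; both forms are
  named explicitly in the API because the +50 % table entry is relative.
- scattering: the scattering-particle density scales with blood volume, so
  Δμs′/μs′ = ΔC_B/C_B exactly.  A Mie power-law form
  μs′ = 3.28πr²ρs(2πr/λ)^0.37(ns/n0−1)^2.09 is provided for deriving μs′
  from particle parameters.

One caveat the implementation surfaces explicitly: applying +50 % to the
upper blood net dermis (C_B = 0.30, C_Other = 0.10) drives C_Other to
−0.05.  The perturbed mixture is then a linear extrapolation of the
mixing rule; `apply_perturbation` warns and flags the layer rather than
rejecting the canonical setting.

## Monte Carlo transport

MCML-style weighted photon transport, compiled with numba: pencil beam at
normal incidence, exponential steps s = −ln ξ/μt, weight deposition
μa/μt per collision, Henyey–Greenstein scattering, unpolarised Fresnel
reflection/refraction at every index mismatch (air/glass, glass/tissue,
interior interfaces, bottom boundary), Russian roulette below weight
10⁻⁴ (survival 0.1).  The glass window is a clear layer traversed by the
leftover-step mechanism.  Detection: photons exiting the top surface are
binned by exit radius into ring detectors at source–detector separations
(SDS) 0.9/1.25/1.7/2.0/2.3 mm, each ring spanning ±0.1 mm about its
centre; all exit angles are accepted.  Photons crossing the bottom of the
subcutaneous layer are terminated as transmitted.

Choices worth recording:

- The specular reflection at the air/glass entry is split deterministically
  (every photon launches with weight 1 − R_sp and R_sp is booked as
  escaped), which removes one source of variance without bias.
- Runs are split into batches (default 10) with seeds derived from a
  `SeedSequence`; results are bit-reproducible for a fixed configuration,
  and standard errors come from the between-batch spread.
- With roulette disabled, a photon reaching the weight threshold deposits
  its residual weight as absorption in the current layer.  The weight
  budget (detected + absorbed + transmitted + escaped = launched) then
  closes exactly per history — observed closure is limited only by
  float64 accumulation (~10⁻¹⁴) — at the cost of a bias bounded by the
  10⁻⁴ threshold.  With roulette enabled the budget closes in expectation.
- Source bands default to monochromatic sampling at the six centre
  wavelengths 1050/1219/1314/1380/1550/1609 nm; Gaussian band sampling
  (σ = FWHM/2.355 over ±2σ) is available for the 3 dB bandwidths
  51/32/36/58/52/57 nm.
- Photon budgets are desk-scale. The instrument-grade reference
  simulation used 10¹⁰ photons; this package defaults to 10⁶ and scales
  the quoted standard errors as 1/√n.  The validation suite uses
  2×10⁵/band for energy closure (closure is budget-independent),
  1.2×10⁶ for the diffusion comparison, and 10⁶ for the perturbation
  spectrum; the acceptance script uses 4×10⁶ for the diffusion
  comparison.

### Validation oracle

`farrell_diffusion_reflectance` implements the steady-state
diffusion-dipole solution for a semi-infinite turbid medium (isotropic
source at one transport mean free path, image source across the
extrapolated boundary with the Groenhuis internal-reflection polynomial).
For μa = 0.1 cm⁻¹, μs′ = 10 cm⁻¹, n_rel = 1.4 the MC kernel agrees with
the closed form within ±10 % over ρ = 2–6 mm (the residual is the known
bias of the diffusion approximation near the source plus MC noise); the
acceptance band is 15 %.  The oracle is used only in tests, never in the
pipeline.

### Differential absorbance and the perturbation spectrum

The working signal is the differential absorbance between two SDS
channels, A_D = ln(I_near/I_far); the incident intensity cancels, so
multiplicative common-mode drift is rejected exactly.  The default pair is
(0.9, 2.3) mm — the widest pair, with the largest differential path
through the vascular dermis — and the pair is explicit metadata on every
spectrum since the measurement depends on it.

The blood-perturbation difference spectrum ΔA_D = A_D(baseline) −
A_D(perturbed) is computed by perturbation Monte Carlo: every detected
photon also scores its history's likelihood ratio under the perturbed
coefficients, (μs′ratio)^k·exp(−Δμt·S) over collisions k and path length
S in the perturbed layers.  Baseline and perturbed estimates therefore
share identical histories; a null perturbation gives exactly zero, the
absorption and scattering channels can be switched independently, and
channel additivity holds to first order in ΔC_B.  Because the likelihood
ratio's variance grows with the collision count, the perturbed layers are
simulated in reduced (isotropic, μs = μs′) representation by default —
consistent with the similarity relation already invoked — which keeps the
+50 % scattering reweighting well conditioned.

## Synthetic study conditions

No measured data ship with the package; the generators encode the study
conditions and are deterministic per seed.

- **Chromophore fixtures.**  The water curve is a sum of Gaussian bands —
  the 1450 nm overtone with an asymmetric red shoulder — chosen to
  approximate pure-water μa at the six bands (≈0.3/1.2/0.7/7.4/7.9/6.7
  cm⁻¹).  "Other" (protein/lipid background) is a scaled water-like curve
  with a 1210 nm lipid bump.  Whole blood exceeds the background by a
  smooth contrast peaking near 1050 nm (oxyhemoglobin overtone, 3.2 cm⁻¹)
  and 1550 nm (water-rich blood against lipid-rich surroundings,
  3.6 cm⁻¹); this contrast is what makes blood-volume changes visible in
  those two bands.  Per-layer μs′ follows decreasing power laws with
  exponents in the mixed Rayleigh–Mie range; the blood-net layers use a
  steeper exponent (1.6), concentrating the blood-scattering signal at
  1050 nm.  All fixtures are replaceable by user CSV tables, and the
  packaged `table1_skin.yaml` reproduces the programmatic defaults.
- **Arm-elevation protocol.**  Raising the forearm 20 cm drains blood from
  the skin; the generator encodes this as the blood-net perturbation
  applied to the skin model, evaluated through a fast homogenised
  diffusion surrogate (depth-weighted effective μa, μs′ with a 1 mm
  exponential kernel), with i.i.d. instrument noise per repeat and three
  repeats per protocol.  The surrogate trades accuracy for speed and is
  not used where transport fidelity matters.
- **OGTT cohorts.**  Reference glucose follows a gamma-variate excursion
  over a subject baseline of 5.0 ± 0.6 mmol/L (peak ≈ +4.5 mmol/L near
  35 min, shape 2.2, returning below 6 mmol/L within the 60–180 min
  window), sampled every 5 min.  The optical signal is
  A_D(t) = α + β·Cg(t) + drift + noise with β = 10⁻³ a.u. per mmol/L, so
  the instrument's 0.001 a.u. stability band corresponds to ≈1 mmol/L.
  Instrument noise is σ = 3·10⁻⁴ a.u.  The reference glucose is the true
  curve plus the mean of two independent meter errors (σ = 0.3 mmol/L
  each).  Blood-flow drift is a logistic onset (lag ≈ 30 min after the
  glucose drink, width 15 min) with per-case amplitude 6·10⁻³·|N(1, 0.5²)|
  a.u. and random sign — an insulin-secretion proxy that exceeds the
  glucose signal, emulating individual variability in postprandial
  vasodilation.  Pre-stimulated cases (blood flow saturated by heating)
  have zero drift; control cases carry it.  The drift's true magnitude in
  A_D units is not established, so it is an explicit parameter.

## OGTT statistics

Per case, glucose is regressed on A_D by ordinary least squares (so
residuals and RMSE are in mmol/L), with Pearson R.  Cohorts are binned at
R > 0.85 / 0.7 / 0.5 with ties falling into the lower bin, plus the
cohort-average RMSE.  Under the default conditions a 24-case
pre-stimulated cohort lands almost entirely in the top bin with average
RMSE ≈ 0.35 mmol/L, while a 21-case control cohort spreads across the
bins (most below R = 0.85) with average RMSE ≈ 1.0 mmol/L; the contrast
(more top-bin cases and lower RMSE under pre-stimulation) holds across
cohort seeds.

A structural note: with this regression direction the in-sample RMSE
cannot exceed the standard deviation of the glucose trace (≈1.5 mmol/L).
Much larger published control-group errors arise only under inverse
calibration — fitting A_D on Cg and inverting the line to predict
glucose, which diverges as the slope estimate approaches zero.  The
package deliberately reports the bounded, better-behaved direct
regression.

## What the synthetic tests do and do not show

The generators demonstrate that the pipeline is correct and that the
qualitative phenomenology (blood/glucose spectral overlap at 1550 nm,
drift-induced correlation loss, the pre-stimulation contrast) follows
from the stated mechanisms.  They do not establish instrument-grade
magnitudes: chromophore fixtures are analytic stand-ins, the drift
amplitude is assumed, the A_D–glucose coupling is linear by construction,
and the ±50 % blood perturbation produces difference spectra an order of
magnitude larger than small postural changes would.  Fig-level
experimental values from human measurements are outside what synthetic
data can reproduce.

## Degenerate inputs and tie-breaks

Non-positive intensities, zero detected ring weights, constant A_D
series, zero-variance spectra, overfilled volume fractions (outside the
flagged extrapolation path), overlapping detector rings and off-grid
wavelengths all raise typed errors rather than propagating NaNs.
Wavelength interpolation is linear on the grid; extrapolation is
forbidden.  R-bin boundary ties go to the lower bin.
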