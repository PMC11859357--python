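# nirskin

Blood-flow interference in near-infrared non-invasive glucose sensing:
a layered-skin diffuse-reflectance simulator and OGTT analysis toolkit.

## The problem

Near-infrared diffuse-reflectance spectroscopy can track blood glucose
through the skin, but the glucose signal is tiny and skin blood flow is a
dominant confounder: vasodilation driven by temperature, emotion or
postprandial insulin changes the blood volume of the dermis, and the
resulting spectral change mimics a glucose change.  One mitigation is
*blood-flow pre-stimulation* — heating the measurement site (~36.5 °C) so
local blood flow saturates before the measurement, leaving later
physiological perturbations with little room to move it.

`nirskin` implements the computational chain needed to study this
quantitatively, exercisable entirely on synthetic data:

- **Seven-layer skin optical model.**  Per-layer absorption from
  chromophore mixing, μa = C_B·μa,B + C_H2O·μa,H2O + C_Other·μa,Other,
  with dedicated stratum-corneum and epidermis formulas; reduced
  scattering per layer; and blood-volume perturbations of the two
  blood-net dermal layers, where Δμa = ΔC_B·(μa,B − μa,Other) and
  Δμs′/μs′ = ΔC_B/C_B exactly.
- **Monte Carlo photon transport** (numba-compiled, MCML-style) through
  the glass-topped stack to ring detectors at SDS 0.9–2.3 mm, with
  Henyey–Greenstein scattering, Fresnel boundaries, Russian roulette,
  batch-seeded reproducibility, and a perturbation-reweighting mode that
  computes baseline and blood-perturbed reflectance from identical photon
  histories.
- **Differential-absorbance analytics.**  A_D = ln(I₁/I₂) between two SDS
  channels (common-mode drift cancels exactly), the paired arm-elevation
  blood-spectrum protocol A_D,blood = A_D0 − A_D1 with repeat averaging,
  and glucose-equivalent conversion of spectral changes.
- **OGTT statistics.**  Per-case OLS calibration of glucose on
  A_D(1550 nm) with Pearson R and RMSE in mmol/L, and cohort summaries
  binned at R > 0.85/0.7/0.5.
- **Synthetic-data generators** for every stage: analytic chromophore and
  scattering fixtures, arm-raise spectra, and OGTT cohorts with
  condition-dependent insulin-coupled blood-flow drift.

See `docs/methods.md` for the models, assumptions and parameter choices.

## Worked example

```python
import numpy as np
from nirskin import (
    MCConfig, PerturbationSpec, blood_perturbation_spectrum,
    default_skin_model, gen_chromophore_fixture,
)

chrom = gen_chromophore_fixture()          # analytic chromophore spectra
model = default_skin_model(chrom)          # the seven-layer skin stack

wl, delta_ad, stderr = blood_perturbation_spectrum(
    model, chrom, PerturbationSpec(delta_CB_rel=0.5),  # +50% blood volume
    channels="both", config=MCConfig(n_photons=400_000, seed=1),
)
for lam, d, s in zip(wl, delta_ad, stderr):
    print(f"{lam:6.0f} nm  dA_D = {d:+.4f} +/- {s:.4f}")
print("peak band:", int(wl[np.argmax(np.abs(delta_ad))]), "nm")
```

prints (seed 1, 4×10⁵ photons per band):

```
  1050 nm  dA_D = -0.0609 +/- 0.0064
  1219 nm  dA_D = -0.0440 +/- 0.0059
  1314 nm  dA_D = -0.0592 +/- 0.0057
  1380 nm  dA_D = -0.0379 +/- 0.0042
  1550 nm  dA_D = -0.0381 +/- 0.0056
  1609 nm  dA_D = -0.0520 +/- 0.0070
peak band: 1050 nm
```

A +50 % blood-volume increase in the blood-net dermal layers shifts the
differential absorbance at every band, most strongly at 1050 nm (blood
absorption and scattering both peak there) with an absorption-channel
feature at 1550 nm — the same band where glucose sensitivity peaks, which
is exactly why uncontrolled blood flow corrupts glucose tracking.

The OGTT side:

```python
from nirskin import OGTTGenParams, fit_case, gen_ogtt_case

params = OGTTGenParams()
for condition in ("pre_stimulated", "control"):
    fit = fit_case(gen_ogtt_case(params, condition, seed=4))
    print(f"{condition:15s} R = {fit.r:+.2f}  RMSE = {fit.rmse:.2f} mmol/L")
```

```
pre_stimulated  R = +0.97  RMSE = 0.32 mmol/L
control         R = +0.22  RMSE = 1.30 mmol/L
```

With pre-stimulated (drift-free) blood flow the optical signal tracks the
glucose excursion almost perfectly; with insulin-coupled blood-flow drift
the correlation collapses and the calibration error grows several-fold
(the drift amplitude and sign vary per case, so individual control cases
range from mildly to severely degraded).

## Analysis scripts

The `analysis/` drivers run the full study narrative and write their
tables under `results/`:

```sh
python analysis/01_skin_optical_model.py   # layer coefficients + perturbation identity
python analysis/02_mc_validation.py        # energy budget + diffusion-dipole check
python analysis/03_blood_spectrum.py       # channel-split dA_D spectra + arm-raise protocol
python analysis/04_ogtt_cohorts.py         # 24 vs 21 case cohorts over 20 seeds
```

A thin CLI wraps the same library calls
(`nirskin simulate|perturb-spectrum|blood-spectrum|ogtt-analyze|synth`).

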