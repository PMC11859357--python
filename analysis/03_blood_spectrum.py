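"""Simulate the blood-flow difference spectrum and its channel split.

Runs the +50% blood-volume perturbation of the blood-net dermal layers
through the transport model with the absorption and scattering channels
separated, then generates the paired arm-elevation protocol (three
repeats) and expresses the averaged blood spectrum in glucose-equivalent
units at 1550 nm.  Writes results/blood_perturbation_spectrum.csv and
results/arm_raise_blood_spectrum.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nirskin.io_utils import write_csv_with_meta
from nirskin.mc_transport import MCConfig, blood_perturbation_spectrum
from nirskin.optical_properties import PerturbationSpec, default_skin_model
from nirskin.spectra_analysis import (
    average_repeats,
    blood_spectrum,
    glucose_equivalent,
    spectral_similarity,
)
from nirskin.synthetic_data import (
    gen_arm_raise_pair,
    gen_chromophore_fixture,
    gen_glucose_sensitivity_fixture,
)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    chrom = gen_chromophore_fixture()
    model = default_skin_model(chrom)
    spec = PerturbationSpec(delta_CB_rel=0.5)
    cfg = MCConfig(n_photons=400_000, seed=SEED)

    frames = {}
    for channel in ("absorption_only", "scattering_only", "both"):
        wl, delta, se = blood_perturbation_spectrum(
            model, chrom, spec, channel, config=cfg
        )
        frames[channel] = (delta, se)
    df = pd.DataFrame({"wavelength_nm": wl})
    for channel, (delta, se) in frames.items():
        df[f"delta_ad_{channel}"] = delta
        df[f"stderr_{channel}"] = se
    write_csv_with_meta(
        OUT / "blood_perturbation_spectrum.csv",
        df,
        {"seed": SEED, "n_photons": cfg.n_photons, "delta_cb_rel": 0.5},
    )
    both = frames["both"][0]
    print("blood perturbation difference spectrum (channels separated):")
    print(df.round(4).to_string(index=False))
    print(f"\npeak |dAD| band: {int(wl[np.argmax(np.abs(both))])} nm")

    pairs = gen_arm_raise_pair(
        model, spec, chrom, noise_sigma=2e-4, seed=SEED, n_repeats=3
    )
    avg = average_repeats(
        [blood_spectrum(a, b) for a, b in pairs], pairs[0][0].wavelengths
    )
    sens = gen_glucose_sensitivity_fixture(avg.wavelengths)
    ge = glucose_equivalent(avg.mean_ad_blood, sens, avg.wavelengths, at=1550.0)
    sim = spectral_similarity(np.abs(avg.mean_ad_blood), sens)
    df = pd.DataFrame(
        {
            "wavelength_nm": avg.wavelengths,
            "mean_ad_blood": avg.mean_ad_blood,
            "std_ad_blood": avg.std_ad_blood,
            "glucose_sensitivity_au_per_mmol": sens,
        }
    )
    write_csv_with_meta(
        OUT / "arm_raise_blood_spectrum.csv",
        df,
        {"seed": SEED, "n_repeats": avg.n_repeats},
    )
    print("\narm-elevation blood spectrum (3-repeat average):")
    print(df.round(5).to_string(index=False))
    print(f"glucose equivalent at 1550 nm: {ge:.1f} mmol/L")
    print(f"|blood spectrum| vs glucose-sensitivity similarity: {sim:.2f}")


if __name__ == "__main__":
    main()
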