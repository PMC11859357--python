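"""Validate the Monte Carlo transport kernel.

Checks (a) the photon weight budget closes when roulette is disabled and
(b) spatially resolved reflectance of a homogeneous semi-infinite medium
matches the diffusion-dipole closed form within its validity band.
Writes results/mc_energy_budget.csv and results/mc_vs_diffusion.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nirskin.io_utils import write_csv_with_meta
from nirskin.mc_transport import (
    DetectorSpec,
    MCConfig,
    SourceSpec,
    default_sources,
    farrell_diffusion_reflectance,
    homogeneous_medium,
    run_mc,
)
from nirskin.optical_properties import default_skin_model
from nirskin.synthetic_data import gen_chromophore_fixture

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    chrom = gen_chromophore_fixture()
    model = default_skin_model(chrom)

    cfg = MCConfig(n_photons=200_000, seed=SEED, roulette_enabled=False)
    res = run_mc(model, chrom, default_sources(), config=cfg)
    budget = pd.DataFrame(
        {
            "wavelength_nm": res.wavelengths,
            "detected": res.detected_weight.sum(axis=1),
            "absorbed": res.absorbed_weight.sum(axis=1),
            "transmitted": res.transmitted_weight,
            "escaped_undetected": res.escaped_undetected_weight,
            "closure_error": res.budget_closure(),
        }
    )
    write_csv_with_meta(
        OUT / "mc_energy_budget.csv",
        budget,
        {"seed": SEED, "n_photons": cfg.n_photons, "roulette": "off"},
    )
    print("energy budget (fractions of launched weight):")
    print(budget.round(6).to_string(index=False))
    print(f"worst closure error: {budget.closure_error.max():.2e}")

    mu_a, msp = 0.1, 10.0
    hmodel, hchrom = homogeneous_medium(mu_a=mu_a, mu_s_prime=msp, n=1.4)
    edges = np.arange(2.0, 6.01, 0.5)
    det = DetectorSpec(ring_centers=tuple((edges[:-1] + edges[1:]) / 2), ring_width=0.5)
    cfg = MCConfig(n_photons=2_000_000, seed=SEED)
    res = run_mc(hmodel, hchrom, SourceSpec(1550.0), det, cfg)
    area = np.pi * ((edges[1:] / 10) ** 2 - (edges[:-1] / 10) ** 2)
    mid = (edges[:-1] + edges[1:]) / 2
    r_mc = res.detected_weight[0] / area
    r_th = farrell_diffusion_reflectance(mu_a, msp, 1.4, mid)
    diff = pd.DataFrame(
        {
            "rho_mm": mid,
            "R_mc_per_cm2": r_mc,
            "R_diffusion_per_cm2": r_th,
            "rel_dev": r_mc / r_th - 1.0,
        }
    )
    write_csv_with_meta(
        OUT / "mc_vs_diffusion.csv",
        diff,
        {"seed": SEED, "n_photons": cfg.n_photons, "mu_a": mu_a, "mu_s_prime": msp},
    )
    print("\nMC vs diffusion dipole (homogeneous medium):")
    print(diff.round(5).to_string(index=False))
    print(f"max |relative deviation|: {np.abs(diff.rel_dev).max():.1%}")


if __name__ == "__main__":
    main()
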