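"""Synthetic inputs for every pipeline stage.

No raw data accompany the measurement campaign this package models, so the
generators here emulate its study conditions: literature-shaped chromophore
and scattering fixtures on the 1000–1700 nm band, paired arm-elevation
spectra (the +50% relative blood-volume perturbation of the two blood-net
dermal layers plus instrument noise, three repeats per protocol), and OGTT
cohorts — a gamma-variate glucose excursion after a 75 g glucose drink,
a linear A_D–glucose coupling, condition-dependent blood-flow drift
(negligible when blood flow is pre-stimulated by heating; insulin-coupled
in the control condition), and two-meter reference-glucose noise.

All generators are deterministic given their seed.  The fixtures are
synthetic stand-ins for untabulated literature spectra: the water curve is
a sum of Gaussian bands dominated by the 1450 nm overtone, the blood and
"other" curves are smooth with a blood−other contrast peaking near 1050
and 1550 nm, and per-layer μs′ follows a decreasing power law.  Any of
them can be replaced by user-supplied CSV tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .mc_transport import DEFAULT_PAIR, farrell_diffusion_reflectance
from .ogtt_analysis import OGTTCase
from .optical_properties import (
    ChromophoreSet,
    PerturbationSpec,
    SkinModel,
    apply_perturbation,
    build_optical_stack,
)
from .spectra_analysis import ADSpectrum

__all__ = [
    "OGTTGenParams",
    "gen_chromophore_fixture",
    "gen_mu_s_fixture",
    "gen_glucose_sensitivity_fixture",
    "gen_glucose_curve",
    "gen_ogtt_case",
    "gen_ogtt_cohort",
    "gen_arm_raise_pair",
    "ad_diffusion_surrogate",
    "MU_S_FIXTURE_PARAMS",
    "DEFAULT_BAND_GRID",
]

DEFAULT_BAND_GRID = np.array([1050.0, 1219.0, 1314.0, 1380.0, 1550.0, 1609.0])

# Per-layer reduced-scattering power law mu_s'(lambda) = a * (lambda/1000)^-b,
# a in cm^-1 at 1000 nm.  Ordering (epidermis most scattering, fat least)
# follows standard skin-optics compilations; the blood-net layers use a
# steeper exponent (blood scatterers sit in the mixed Rayleigh-Mie regime),
# which concentrates the blood-scattering signal in the 1050 nm band.
MU_S_FIXTURE_PARAMS: dict[str, tuple[float, float]] = {
    "stratum_corneum": (45.0, 1.4),
    "living_epidermis": (40.0, 1.3),
    "papillary_dermis": (30.0, 1.2),
    "upper_blood_net_dermis": (22.0, 1.6),
    "reticular_dermis": (18.0, 1.1),
    "deep_blood_net_dermis": (16.0, 1.6),
    "subcutaneous_tissue": (13.0, 0.9),
}


def _gauss(lam: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((lam - center) / width) ** 2))


def gen_chromophore_fixture(grid: np.ndarray | None = None) -> ChromophoreSet:
    """Analytic chromophore spectra on ``grid`` (nm), default 1000–1700.

    Water carries the dominant 1450 nm absorption band with the rising
    shoulder toward 1700 nm; "other" (protein/lipid background) is a scaled
    water-like curve with a lipid-ish 1210 nm bump; blood exceeds "other"
    by a smooth contrast with maxima near 1050 and 1550 nm, which is what
    makes blood-volume changes visible in those bands.
    """
    if grid is None:
        grid = np.arange(1000.0, 1701.0, 5.0)
    lam = np.asarray(grid, dtype=float)
    # 1450 nm overtone plus the asymmetric red shoulder toward 1600 nm;
    # approximates pure-water mu_a at the six instrument bands
    water = (
        0.32
        + 24.0 * _gauss(lam, 1450.0, 60.0)
        + 1.1 * _gauss(lam, 1190.0, 55.0)
        + 6.5 * _gauss(lam, 1590.0, 150.0)
    )
    other = 0.35 * water + 0.6 + 0.8 * _gauss(lam, 1210.0, 60.0)
    # whole-blood excess over the background: oxyhemoglobin overtone near
    # 1050 nm and the water-rich-blood band near 1550 nm, peak magnitudes
    # a few cm^-1 as for whole blood against bloodless dermis
    contrast = (
        0.2 + 3.2 * _gauss(lam, 1050.0, 60.0) + 3.6 * _gauss(lam, 1550.0, 65.0)
    )
    blood = other + contrast
    return ChromophoreSet(
        wavelengths=lam, mu_a_water=water, mu_a_blood=blood, mu_a_other=other
    )


def gen_mu_s_fixture(layer_name: str, grid: np.ndarray) -> np.ndarray:
    """Power-law reduced-scattering spectrum (cm⁻¹) for a named layer."""
    try:
        a, b = MU_S_FIXTURE_PARAMS[layer_name]
    except KeyError:
        raise KeyError(
            f"no scattering fixture for layer {layer_name!r}; "
            f"known: {sorted(MU_S_FIXTURE_PARAMS)}"
        ) from None
    lam = np.asarray(grid, dtype=float)
    return a * (lam / 1000.0) ** -b


def gen_glucose_sensitivity_fixture(grid: np.ndarray | None = None) -> np.ndarray:
    """A_D change per 1 mmol/L glucose (a.u.), peaking near 1550 nm.

    Synthetic stand-in for the measured glucose sensitivity spectrum;
    magnitude of order 10⁻³ a.u. per mmol/L at the peak.
    """
    lam = np.asarray(
        grid if grid is not None else DEFAULT_BAND_GRID, dtype=float
    )
    return 1.0e-3 * _gauss(lam, 1550.0, 75.0) + 1.0e-4


# --------------------------------------------------------------------------
# OGTT generators
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OGTTGenParams:
    """Study-condition parameters of the OGTT generator.

    Baseline glucose 5.0 ± 0.6 mmol/L, 5-min sampling over 1–3 h, a
    gamma-variate excursion peaking ~35 min after the glucose drink and
    returning below 6 mmol/L by the end, A_D coupling of order 10⁻³ a.u.
    per mmol/L (so the instrument's 0.001 a.u. stability band corresponds
    to ~1 mmol/L), and an insulin-coupled logistic blood-flow drift in the
    control condition whose amplitude exceeds the glucose signal.
    """

    baseline_cg: float = 5.0  # mmol/L
    baseline_sd: float = 0.6  # mmol/L, between-subject dispersion
    peak_rise: float = 4.5  # mmol/L mean excursion amplitude
    peak_rise_sd: float = 1.0
    t_peak_min: float = 35.0  # minutes to excursion peak
    t_peak_sd: float = 8.0
    shape: float = 2.2  # gamma-variate shape exponent
    coupling_beta: float = 1.0e-3  # a.u. per mmol/L
    coupling_alpha: float = 0.01  # a.u. offset
    noise_sigma_ad: float = 3.0e-4  # a.u.
    drift_amplitude: float = 6.0e-3  # a.u., control condition
    drift_amplitude_cv: float = 0.5  # per-case amplitude spread
    drift_lag_min: float = 30.0
    drift_lag_sd: float = 10.0
    drift_width_min: float = 15.0
    glucometer_sigma: float = 0.3  # mmol/L per meter reading
    duration_min: float = 120.0
    sample_interval_min: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "baseline_cg",
            "peak_rise",
            "t_peak_min",
            "shape",
            "duration_min",
            "sample_interval_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (60.0 <= self.duration_min <= 180.0):
            raise ValueError("duration must lie in the 60–180 min protocol window")


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_glucose_curve(
    params: OGTTGenParams, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Reference glucose trajectory (time in minutes, Cg in mmol/L).

    Gamma-variate excursion over a subject baseline:
    Cg(t) = B + A·(t/tp)^p·exp(p·(1 − t/tp)); equals B at t = 0 and decays
    back toward B, ending below 6 mmol/L under the default parameters.
    """
    rng = _rng(seed)
    t = np.arange(0.0, params.duration_min + 1e-9, params.sample_interval_min)
    baseline = params.baseline_cg + params.baseline_sd * rng.standard_normal()
    amp = max(params.peak_rise + params.peak_rise_sd * rng.standard_normal(), 0.0)
    tp = float(
        np.clip(params.t_peak_min + params.t_peak_sd * rng.standard_normal(), 20.0, 50.0)
    )
    p = params.shape
    with np.errstate(divide="ignore", invalid="ignore"):
        shape = np.where(t > 0, (t / tp) ** p * np.exp(p * (1.0 - t / tp)), 0.0)
    return t, baseline + amp * shape


def _drift(
    t: np.ndarray, params: OGTTGenParams, rng: np.random.Generator
) -> np.ndarray:
    """Insulin-coupled blood-flow drift: logistic onset after a lag.

    Amplitude (sign and magnitude) varies per case, emulating individual
    variability in postprandial vasodilation.
    """
    amp = (
        params.drift_amplitude
        * abs(1.0 + params.drift_amplitude_cv * rng.standard_normal())
        * rng.choice((-1.0, 1.0))
    )
    lag = max(params.drift_lag_min + params.drift_lag_sd * rng.standard_normal(), 10.0)
    width = max(params.drift_width_min, 5.0)
    return amp * expit((t - lag) / width)


def gen_ogtt_case(
    params: OGTTGenParams,
    condition: str = "pre_stimulated",
    seed: int | np.random.Generator = 0,
    subject_meta: dict | None = None,
) -> OGTTCase:
    """One synthetic OGTT case.

    A_D(t) = α + β·Cg(t) + drift(t; condition) + N(0, σ_ad); the glucose
    reference is the true curve plus the mean of two independent meter
    errors.  ``pre_stimulated`` sets the drift to zero (blood flow
    saturated by heating); ``control`` applies the insulin-coupled drift.
    """
    rng = _rng(seed)
    t, cg_true = gen_glucose_curve(params, rng)
    drift = np.zeros_like(t) if condition == "pre_stimulated" else _drift(t, params, rng)
    ad = (
        params.coupling_alpha
        + params.coupling_beta * cg_true
        + drift
        + params.noise_sigma_ad * rng.standard_normal(t.size)
    )
    meter = rng.normal(0.0, params.glucometer_sigma, size=(2, t.size))
    cg_ref = np.maximum(cg_true + meter.mean(axis=0), 0.1)
    return OGTTCase(
        time=t,
        cg=cg_ref,
        ad_1550=ad,
        condition=condition,
        subject_meta=subject_meta or {},
    )


def gen_ogtt_cohort(
    params: OGTTGenParams,
    condition: str,
    n_cases: int,
    seed: int = 0,
) -> list[OGTTCase]:
    """Independent cases for one condition, seeded per case."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(0 if condition == "pre_stimulated" else 1,))
    return [
        gen_ogtt_case(params, condition, np.random.default_rng(child), {"case": i})
        for i, child in enumerate(ss.spawn(n_cases))
    ]


# --------------------------------------------------------------------------
# arm-elevation paired spectra
# --------------------------------------------------------------------------

def ad_diffusion_surrogate(
    model: SkinModel,
    chromophores: ChromophoreSet,
    lam: float,
    pair: tuple[float, float] = DEFAULT_PAIR,
    depth_scale_cm: float = 0.1,
) -> float:
    """Fast analytic A_D for a layered model via a homogenised diffusion dipole.

    The stack is collapsed to effective (μa, μs′) by depth-weighted
    averaging with an exponential kernel of scale ``depth_scale_cm``
    (shallow layers dominate at millimetre SDS), then
    A_D = ln(R(ρ_near)/R(ρ_far)) from the diffusion closed form.  A cheap
    stand-in for the MC path used where many repeats are generated.
    """
    stack = build_optical_stack(model, chromophores, lam)
    z = 0.0
    w_sum = 0.0
    mu_a_eff = 0.0
    msp_eff = 0.0
    for props in stack:
        z_mid = z + props.thickness / 2.0
        w = props.thickness * np.exp(-z_mid / depth_scale_cm)
        mu_a_eff += w * props.mu_a
        msp_eff += w * props.mu_s_prime
        w_sum += w
        z += props.thickness
    mu_a_eff /= w_sum
    msp_eff /= w_sum
    n_rel = model.layers[0].n / model.ambient_n
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        r_near = farrell_diffusion_reflectance(mu_a_eff, msp_eff, n_rel, pair[0])
        r_far = farrell_diffusion_reflectance(mu_a_eff, msp_eff, n_rel, pair[1])
    return float(np.log(r_near / r_far))


def gen_arm_raise_pair(
    model: SkinModel,
    spec: PerturbationSpec,
    chromophores: ChromophoreSet,
    noise_sigma: float = 2.0e-4,
    seed: int | np.random.Generator = 0,
    n_repeats: int = 3,
    wavelengths: np.ndarray | None = None,
    pair: tuple[float, float] = DEFAULT_PAIR,
) -> list[tuple[ADSpectrum, ADSpectrum]]:
    """Paired arm-position spectra: (A_D0 at heart level, A_D1 elevated) × repeats.

    Elevating the forearm drains blood from the skin; its signal-level
    effect is encoded as the blood-net perturbation ``spec`` applied to the
    skin model.  Each repeat adds i.i.d. instrument noise of SD
    ``noise_sigma`` (a.u.) to both spectra.
    """
    rng = _rng(seed)
    lam_grid = np.asarray(
        wavelengths if wavelengths is not None else DEFAULT_BAND_GRID, dtype=float
    )
    perturbed = apply_perturbation(model, spec)
    ad0_clean = np.array(
        [ad_diffusion_surrogate(model, chromophores, lam, pair) for lam in lam_grid]
    )
    ad1_clean = np.array(
        [ad_diffusion_surrogate(perturbed, chromophores, lam, pair) for lam in lam_grid]
    )
    pairs = []
    for rep in range(n_repeats):
        ad0 = ADSpectrum(
            wavelengths=lam_grid,
            ad=ad0_clean + noise_sigma * rng.standard_normal(lam_grid.size),
            pair=pair,
            meta={"position": "heart_level", "repeat": rep},
        )
        ad1 = ADSpectrum(
            wavelengths=lam_grid,
            ad=ad1_clean + noise_sigma * rng.standard_normal(lam_grid.size),
            pair=pair,
            meta={"position": "elevated_20cm", "repeat": rep},
        )
        pairs.append((ad0, ad1))
    return pairs
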