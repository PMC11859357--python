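"""Per-layer absorption and reduced-scattering coefficients for layered skin.

The skin is modelled as a seven-layer stack (stratum corneum, living
epidermis, papillary dermis, upper blood net dermis, reticular dermis, deep
blood net dermis, subcutaneous tissue) under a glass probe window.  Each
layer's absorption coefficient is mixed from chromophore spectra — water,
whole blood and the remaining "other" tissue components — weighted by the
layer's volume fractions C_B (blood), C_H2O (interstitial water) and
C_Other = 1 − C_B − C_H2O.  Reduced scattering follows a Mie power-law
approximation in which μs′ is proportional to the scattering-particle
density, so a relative blood-volume change ΔC_B/C_B maps onto an identical
relative change of μs′.

Blood-volume perturbations (vasodilation/vasoconstriction) are applied only
to the two vascularised dermal layers — the upper and deep blood net dermis —
with all other layers held fixed and interstitial water content constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ChromophoreSet",
    "SkinLayer",
    "SkinModel",
    "PerturbationSpec",
    "LayerOpticalProperties",
    "mu_a_stratum_corneum",
    "mu_a_living_epidermis",
    "mu_a_dermal",
    "delta_mu_a",
    "mu_s_prime_graaff",
    "delta_mu_s_prime",
    "build_optical_stack",
    "apply_perturbation",
    "default_skin_model",
    "TABLE_LAYERS",
]

# Canonical layer parameters of the seven-layer model:
# (name, kind, thickness_cm, C_B, C_H2O)
TABLE_LAYERS: tuple[tuple[str, str, float, float, float], ...] = (
    ("stratum_corneum", "stratum_corneum", 0.002, 0.00, 0.05),
    ("living_epidermis", "living_epidermis", 0.008, 0.00, 0.20),
    ("papillary_dermis", "dermal", 0.020, 0.04, 0.50),
    ("upper_blood_net_dermis", "dermal", 0.010, 0.30, 0.60),
    ("reticular_dermis", "dermal", 0.160, 0.04, 0.70),
    ("deep_blood_net_dermis", "dermal", 0.012, 0.10, 0.70),
    ("subcutaneous_tissue", "subcutaneous", 0.650, 0.05, 0.70),
)

BLOOD_NET_LAYERS = frozenset({"upper_blood_net_dermis", "deep_blood_net_dermis"})

_KINDS = {"stratum_corneum", "living_epidermis", "dermal", "subcutaneous"}
_BLOODLESS_KINDS = {"stratum_corneum", "living_epidermis"}

WAVELENGTH_MIN_NM = 1000.0
WAVELENGTH_MAX_NM = 1700.0


class InvalidInputError(ValueError):
    """A physical precondition on an optical-property argument is violated."""


class InvalidPerturbationError(ValueError):
    """A blood-volume perturbation would leave the physical parameter range."""


@dataclass(frozen=True)
class ChromophoreSet:
    """Absorption spectra of the three tissue chromophore groups.

    All spectra share one ascending wavelength grid (nm) inside
    [1000, 1700] and are in cm⁻¹.  ``mu_a_other`` is the lumped absorption
    of everything that is neither water nor whole blood.
    """

    wavelengths: np.ndarray
    mu_a_water: np.ndarray
    mu_a_blood: np.ndarray
    mu_a_other: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        for name in ("mu_a_water", "mu_a_blood", "mu_a_other"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != wl.shape:
                raise InvalidInputError(
                    f"{name} grid shape {arr.shape} != wavelength grid {wl.shape}"
                )
            if np.any(arr < 0):
                raise InvalidInputError(f"{name} has negative values")
        if wl.ndim != 1 or wl.size < 2:
            raise InvalidInputError("wavelength grid must be 1-D with >= 2 points")
        if np.any(np.diff(wl) <= 0):
            raise InvalidInputError("wavelength grid must be strictly ascending")

    def _interp(self, spectrum: np.ndarray, lam: float | np.ndarray) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        if np.any(lam < self.wavelengths[0]) or np.any(lam > self.wavelengths[-1]):
            raise InvalidInputError(
                f"wavelength {lam} outside chromophore grid "
                f"[{self.wavelengths[0]}, {self.wavelengths[-1]}] nm"
            )
        return np.interp(lam, self.wavelengths, spectrum)

    def water(self, lam: float | np.ndarray) -> np.ndarray:
        """μa of pure water at ``lam`` nm (linear interpolation on the grid)."""
        return self._interp(self.mu_a_water, lam)

    def blood(self, lam: float | np.ndarray) -> np.ndarray:
        return self._interp(self.mu_a_blood, lam)

    def other(self, lam: float | np.ndarray) -> np.ndarray:
        return self._interp(self.mu_a_other, lam)


@dataclass(frozen=True)
class SkinLayer:
    """One layer of the skin stack.

    ``mu_s_prime`` is the reduced scattering spectrum (cm⁻¹) on the same
    wavelength grid as the chromophore set used with the layer; ``g`` and
    ``n`` are the scattering anisotropy and refractive index used by the
    transport step (not given by the layer table; standard skin-optics
    defaults are applied by :func:`default_skin_model`).
    """

    name: str
    kind: str
    thickness: float  # cm
    C_B: float
    C_H2O: float
    mu_s_prime: np.ndarray  # cm⁻¹ per wavelength grid point
    g: float = 0.9
    n: float = 1.37
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InvalidInputError(f"unknown layer kind {self.kind!r}")
        if not (self.thickness > 0):
            raise InvalidInputError(f"{self.name}: thickness must be > 0")
        for frac, label in ((self.C_B, "C_B"), (self.C_H2O, "C_H2O")):
            if not (0.0 <= frac <= 1.0):
                raise InvalidInputError(f"{self.name}: {label}={frac} outside [0, 1]")
        # the +50% blood perturbation of the canonical layer table overfills
        # the volume budget (C_Other < 0); apply_perturbation marks such
        # layers as extrapolated instead of rejecting them
        if self.C_B + self.C_H2O > 1.0 + 1e-12 and not self.extrapolated:
            raise InvalidInputError(
                f"{self.name}: C_B + C_H2O = {self.C_B + self.C_H2O} > 1"
            )
        if self.kind in _BLOODLESS_KINDS and self.C_B != 0.0:
            raise InvalidInputError(f"{self.name}: {self.kind} must have C_B = 0")
        if not (-1.0 < self.g < 1.0):
            raise InvalidInputError(f"{self.name}: anisotropy g={self.g} outside (-1, 1)")
        if not (self.n > 1.0):
            raise InvalidInputError(f"{self.name}: refractive index must exceed 1")
        msp = np.asarray(self.mu_s_prime, dtype=float)
        object.__setattr__(self, "mu_s_prime", msp)
        if np.any(msp <= 0):
            raise InvalidInputError(f"{self.name}: mu_s_prime must be > 0 everywhere")

    @property
    def C_Other(self) -> float:
        return 1.0 - self.C_H2O - self.C_B


@dataclass(frozen=True)
class SkinModel:
    """Ordered layer stack (top to bottom) under a glass probe window."""

    layers: tuple[SkinLayer, ...]
    superstrate_n: float = 1.4
    superstrate_thickness: float = 0.02  # cm
    ambient_n: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if not self.layers:
            raise InvalidInputError("skin model needs at least one layer")
        if self.superstrate_thickness < 0:
            raise InvalidInputError("superstrate thickness must be >= 0")

    @property
    def total_depth(self) -> float:
        """Total tissue depth in cm (sum of layer thicknesses)."""
        return float(sum(layer.thickness for layer in self.layers))

    def layer_named(self, name: str) -> SkinLayer:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise KeyError(name)


@dataclass(frozen=True)
class PerturbationSpec:
    """Relative blood-volume change applied to the blood-net dermal layers.

    ``delta_CB_rel`` is ΔC_B/C_B (the layer table's "+50%" is 0.5); the
    displaced volume is taken from the "other" components with coupling
    ``k`` (ΔC_Other = k·ΔC_B, k = −1 keeps C_H2O fixed).
    """

    target_layers: frozenset[str] = frozenset(BLOOD_NET_LAYERS)
    delta_CB_rel: float = 0.5
    k: float = -1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_layers", frozenset(self.target_layers))
        if not np.isfinite(self.k):
            raise InvalidInputError("coupling k must be finite")


@dataclass(frozen=True)
class LayerOpticalProperties:
    """Transport-ready coefficients for one layer at one wavelength."""

    name: str
    mu_a: float  # cm⁻¹
    mu_s: float  # cm⁻¹
    g: float
    n: float
    thickness: float  # cm

    @property
    def mu_s_prime(self) -> float:
        return self.mu_s * (1.0 - self.g)


# --------------------------------------------------------------------------
# absorption models
# --------------------------------------------------------------------------

def mu_a_stratum_corneum(
    lam: float | np.ndarray,
    mu_a_other: float | np.ndarray,
    *,
    linear_coeff_per_um: float = 8.3e-4,
    floor: float = 0.0,
) -> np.ndarray:
    """Absorption coefficient of the stratum corneum (cm⁻¹).

    μa(λ) = 0.1 − c·λ[µm] + 0.125·μaOther(λ), with the linear term taken in
    micrometres: evaluated in nanometres the term would exceed the constant
    by three orders of magnitude and force μa negative across the whole
    1000–1700 nm band.  The convention is exposed through
    ``linear_coeff_per_um`` and guarded by a non-negativity ``floor``
    (applied with a warning).
    """
    lam = np.asarray(lam, dtype=float)
    mu_a_other = np.asarray(mu_a_other, dtype=float)
    _check_band(lam)
    if np.any(mu_a_other < 0):
        raise InvalidInputError("mu_a_other must be >= 0")
    if floor < 0:
        raise InvalidInputError("floor must be >= 0")
    out = 0.1 - linear_coeff_per_um * (lam / 1000.0) + 0.125 * mu_a_other
    if np.any(out < floor):
        warnings.warn(
            "stratum-corneum mu_a fell below the configured floor; clipping",
            RuntimeWarning,
            stacklevel=2,
        )
        out = np.maximum(out, floor)
    return out if out.ndim else float(out)


def mu_a_living_epidermis(
    lam: float | np.ndarray,
    C_H2O: float,
    mu_a_water: float | np.ndarray,
) -> np.ndarray:
    """Absorption coefficient of the living epidermis (cm⁻¹).

    A λ^−3.33 background (λ in nm) for the non-aqueous volume plus the
    water contribution: 0.5·10¹⁰·λ⁻³·³³·(1−C_H2O) + C_H2O·μaH2O(λ).
    """
    lam = np.asarray(lam, dtype=float)
    _check_band(lam)
    if not (0.0 <= C_H2O <= 1.0):
        raise InvalidInputError(f"C_H2O={C_H2O} outside [0, 1]")
    out = 0.5e10 * lam**-3.33 * (1.0 - C_H2O) + C_H2O * np.asarray(mu_a_water, float)
    return out if out.ndim else float(out)


def mu_a_dermal(
    lam: float | np.ndarray,
    C_B: float,
    C_H2O: float,
    chromophores: ChromophoreSet,
    *,
    allow_extrapolated: bool = False,
) -> np.ndarray:
    """Volume-fraction mixture μa for dermal and subcutaneous layers (cm⁻¹).

    C_B·μaB + C_H2O·μaH2O + (1 − C_H2O − C_B)·μaOther at ``lam``.
    ``allow_extrapolated`` accepts C_B + C_H2O > 1 (negative C_Other),
    evaluating the mixture as a linear extrapolation — needed for the
    canonical +50% blood perturbation, which overfills the volume budget.
    """
    if not (0.0 <= C_B <= 1.0 and 0.0 <= C_H2O <= 1.0):
        raise InvalidInputError("volume fractions must lie in [0, 1]")
    if C_B + C_H2O > 1.0 + 1e-12 and not allow_extrapolated:
        raise InvalidInputError(f"C_B + C_H2O = {C_B + C_H2O} > 1")
    out = (
        C_B * chromophores.blood(lam)
        + C_H2O * chromophores.water(lam)
        + (1.0 - C_H2O - C_B) * chromophores.other(lam)
    )
    return out if np.ndim(out) else float(out)


def delta_mu_a(
    delta_CB_abs: float,
    chromophores: ChromophoreSet,
    k: float = -1.0,
    lam: float | np.ndarray | None = None,
) -> np.ndarray:
    """Absorption change of a blood-net layer for an ABSOLUTE ΔC_B.

    Δμa = ΔC_B·μaB + k·ΔC_B·μaOther per wavelength (ΔC_Other = k·ΔC_B;
    interstitial water held constant).  With k = −1 this equals the exact
    finite difference of :func:`mu_a_dermal` at fixed C_H2O.  Note the
    argument is the absolute fraction change: a layer-table "+50%" on a
    layer with C_B means ``delta_CB_abs = 0.5 * C_B``.
    """
    if not np.isfinite(k):
        raise InvalidInputError("coupling k must be finite")
    if lam is None:
        blood = chromophores.mu_a_blood
        other = chromophores.mu_a_other
    else:
        blood = chromophores.blood(lam)
        other = chromophores.other(lam)
    out = delta_CB_abs * blood + k * delta_CB_abs * other
    return out if np.ndim(out) else float(out)


# --------------------------------------------------------------------------
# scattering models
# --------------------------------------------------------------------------

def mu_s_prime_graaff(
    r_um: float,
    rho_s_per_cm3: float,
    lam_nm: float | np.ndarray,
    n_s: float,
    n_0: float,
) -> np.ndarray:
    """Reduced scattering from the Mie power-law approximation (cm⁻¹).

    μs′ = 3.28·π·r²·ρs·(2πr/λ)^0.37·(n_s/n_0 − 1)^2.09 with r and λ
    converted to centimetres so the result carries ρs's cm⁻³.
    """
    if r_um <= 0 or rho_s_per_cm3 <= 0:
        raise InvalidInputError("particle radius and density must be > 0")
    if not (n_s > n_0 > 0):
        raise InvalidInputError(
            "need n_s > n_0 > 0 (fractional power of a non-positive base)"
        )
    r_cm = r_um * 1e-4
    lam_cm = np.asarray(lam_nm, dtype=float) * 1e-7
    out = (
        3.28
        * np.pi
        * r_cm**2
        * rho_s_per_cm3
        * (2.0 * np.pi * r_cm / lam_cm) ** 0.37
        * (n_s / n_0 - 1.0) ** 2.09
    )
    return out if np.ndim(out) else float(out)


def delta_mu_s_prime(
    mu_s_prime: float | np.ndarray, delta_CB_rel: float
) -> np.ndarray:
    """Scattering change for a relative blood-volume change.

    The scattering-particle density scales with blood volume, so
    Δμs′ = μs′·(ΔC_B/C_B): the relative scattering change equals the
    relative blood-fraction change exactly.
    """
    msp = np.asarray(mu_s_prime, dtype=float)
    if np.any(msp <= 0):
        raise InvalidInputError("mu_s_prime must be > 0")
    out = msp * delta_CB_rel
    return out if np.ndim(out) else float(out)


# --------------------------------------------------------------------------
# stack assembly and perturbation
# --------------------------------------------------------------------------

def _check_band(lam: np.ndarray) -> None:
    if np.any(lam < WAVELENGTH_MIN_NM) or np.any(lam > WAVELENGTH_MAX_NM):
        raise InvalidInputError(
            f"wavelength outside the [{WAVELENGTH_MIN_NM:.0f}, "
            f"{WAVELENGTH_MAX_NM:.0f}] nm model band"
        )


def _layer_mu_s_prime_at(
    layer: SkinLayer, chromophores: ChromophoreSet, lam: float
) -> float:
    """Interpolate the layer's μs′ spectrum (tabulated on the chromophore grid)."""
    if layer.mu_s_prime.shape != chromophores.wavelengths.shape:
        raise InvalidInputError(
            f"{layer.name}: mu_s_prime grid does not match the chromophore grid"
        )
    return float(chromophores._interp(layer.mu_s_prime, lam))


def build_optical_stack(
    model: SkinModel,
    chromophores: ChromophoreSet,
    lam: float,
) -> list[LayerOpticalProperties]:
    """Transport-ready (μa, μs, g, n) per layer at one wavelength.

    Dispatches on layer kind to the matching absorption formula and converts
    reduced scattering through the similarity relation μs = μs′/(1 − g).
    """
    stack: list[LayerOpticalProperties] = []
    for layer in model.layers:
        if layer.kind == "stratum_corneum":
            mu_a = float(mu_a_stratum_corneum(lam, chromophores.other(lam)))
        elif layer.kind == "living_epidermis":
            mu_a = float(
                mu_a_living_epidermis(lam, layer.C_H2O, chromophores.water(lam))
            )
        else:  # dermal and subcutaneous share the mixture rule
            mu_a = float(
                mu_a_dermal(
                    lam,
                    layer.C_B,
                    layer.C_H2O,
                    chromophores,
                    allow_extrapolated=layer.extrapolated,
                )
            )
        msp = _layer_mu_s_prime_at(layer, chromophores, lam)
        mu_s = msp / (1.0 - layer.g)
        stack.append(
            LayerOpticalProperties(
                name=layer.name,
                mu_a=mu_a,
                mu_s=mu_s,
                g=layer.g,
                n=layer.n,
                thickness=layer.thickness,
            )
        )
    return stack


def apply_perturbation(model: SkinModel, spec: PerturbationSpec) -> SkinModel:
    """Return a new model with blood volume changed in the target layers.

    Targeted layers get C_B scaled by (1 + ΔC_B_rel) and μs′ scaled by the
    same factor; C_H2O is unchanged (the displaced volume trades against the
    "other" components).  Untargeted layers are passed through unchanged.
    """
    missing = set(spec.target_layers) - {layer.name for layer in model.layers}
    if missing:
        raise InvalidPerturbationError(f"unknown target layers: {sorted(missing)}")
    new_layers = []
    for layer in model.layers:
        if layer.name not in spec.target_layers:
            new_layers.append(layer)
            continue
        if layer.C_B <= 0:
            raise InvalidPerturbationError(
                f"{layer.name}: cannot apply a relative blood change to a "
                "layer with C_B = 0"
            )
        new_CB = layer.C_B * (1.0 + spec.delta_CB_rel)
        delta_abs = new_CB - layer.C_B
        new_COther = layer.C_Other + spec.k * delta_abs
        if not (0.0 <= new_CB <= 1.0):
            raise InvalidPerturbationError(
                f"{layer.name}: perturbed C_B={new_CB:.4f} leaves [0, 1]"
            )
        extrapolated = bool(new_COther < 0.0 or new_CB + layer.C_H2O > 1.0)
        if extrapolated:
            warnings.warn(
                f"{layer.name}: perturbed C_Other={new_COther:.3f} < 0; the "
                "mixture rule is evaluated as a linear extrapolation",
                RuntimeWarning,
                stacklevel=2,
            )
        new_layers.append(
            replace(
                layer,
                C_B=new_CB,
                mu_s_prime=layer.mu_s_prime * (1.0 + spec.delta_CB_rel),
                extrapolated=extrapolated,
            )
        )
    return replace(model, layers=tuple(new_layers))


def default_skin_model(
    chromophores: ChromophoreSet,
    *,
    g: float = 0.9,
    n: float = 1.37,
) -> SkinModel:
    """The canonical seven-layer model with fixture μs′ spectra.

    Layer thicknesses and blood/water fractions follow the standard layer
    table; anisotropy and refractive index (not specified by the table) use
    standard skin-optics defaults, uniform across layers unless overridden
    per layer afterwards.
    """
    from .synthetic_data import gen_mu_s_fixture

    layers = tuple(
        SkinLayer(
            name=name,
            kind=kind,
            thickness=thickness,
            C_B=cb,
            C_H2O=ch2o,
            mu_s_prime=gen_mu_s_fixture(name, chromophores.wavelengths),
            g=g,
            n=n,
        )
        for name, kind, thickness, cb, ch2o in TABLE_LAYERS
    )
    return SkinModel(layers=layers)
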