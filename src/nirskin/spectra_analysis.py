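"""Measurement algebra for dual-distance diffuse-reflectance spectra.

The instrument injects light at one point and reads diffusely reflected
intensity at several source–detector separations (SDS).  Absorbance at a
single SDS depends on the incident intensity I0 and therefore drifts with
the source; the differential absorbance between two SDS channels,
A_D = ln(I1/I2), cancels I0 and every other multiplicative common-mode
factor.  A_D is the working signal throughout: blood-volume changes are
extracted as the difference of A_D between two arm positions, and glucose
tracking correlates A_D at 1550 nm against reference glucose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ADSpectrum",
    "BloodSpectrum",
    "absorbance",
    "differential_absorbance",
    "blood_spectrum",
    "average_repeats",
    "glucose_equivalent",
    "spectral_similarity",
]


class IntensityError(ValueError):
    """Non-positive intensity where a logarithm is required."""


class GridMismatchError(ValueError):
    """Spectra that must share a wavelength grid or detector pair do not."""


@dataclass(frozen=True)
class ADSpectrum:
    """Differential absorbance per wavelength for one detector pair.

    ``pair`` is the (near, far) ring-centre SDS in mm; it is carried as
    explicit metadata because A_D depends on which two channels were
    differenced.
    """

    wavelengths: np.ndarray  # nm
    ad: np.ndarray  # a.u.
    pair: tuple[float, float]
    stderr: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ad = np.asarray(self.ad, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "ad", ad)
        if wl.shape != ad.shape:
            raise GridMismatchError("wavelength and A_D arrays differ in shape")
        if not np.all(np.isfinite(ad)):
            raise ValueError("A_D values must be finite")
        if self.stderr is not None:
            se = np.asarray(self.stderr, dtype=float)
            object.__setattr__(self, "stderr", se)
            if se.shape != wl.shape:
                raise GridMismatchError("stderr grid does not match wavelengths")

    def at(self, lam: float) -> float:
        """A_D interpolated at ``lam`` nm (linear, no extrapolation)."""
        if lam < self.wavelengths.min() or lam > self.wavelengths.max():
            raise GridMismatchError(f"{lam} nm outside the spectrum grid")
        return float(np.interp(lam, self.wavelengths, self.ad))


@dataclass(frozen=True)
class BloodSpectrum:
    """Repeat-averaged blood-volume difference spectrum (mean ± SD)."""

    wavelengths: np.ndarray
    mean_ad_blood: np.ndarray
    std_ad_blood: np.ndarray
    n_repeats: int

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("need at least one repeat")
        if np.any(np.asarray(self.std_ad_blood) < 0):
            raise ValueError("standard deviations must be >= 0")


def absorbance(I: float | np.ndarray, I0: float | np.ndarray) -> np.ndarray:
    """Single-channel absorbance −ln(I/I0)."""
    I = np.asarray(I, dtype=float)
    I0 = np.asarray(I0, dtype=float)
    if np.any(I <= 0) or np.any(I0 <= 0):
        raise IntensityError("intensities must be strictly positive")
    out = -np.log(I / I0)
    return out if out.ndim else float(out)


def differential_absorbance(
    I1: float | np.ndarray, I2: float | np.ndarray
) -> np.ndarray:
    """A_D = A2 − A1 = ln(I1/I2): the dual-distance differential signal.

    The incident intensity cancels, so any common multiplicative drift of
    the two channels (source power, coupling) is rejected exactly.
    """
    I1 = np.asarray(I1, dtype=float)
    I2 = np.asarray(I2, dtype=float)
    if np.any(I1 <= 0) or np.any(I2 <= 0):
        raise IntensityError("intensities must be strictly positive")
    out = np.log(I1 / I2)
    return out if out.ndim else float(out)


def _check_compatible(ad0: ADSpectrum, ad1: ADSpectrum) -> None:
    if ad0.wavelengths.shape != ad1.wavelengths.shape or not np.allclose(
        ad0.wavelengths, ad1.wavelengths
    ):
        raise GridMismatchError("A_D spectra are on different wavelength grids")
    if ad0.pair != ad1.pair:
        raise GridMismatchError(
            f"A_D spectra use different detector pairs {ad0.pair} vs {ad1.pair}"
        )


def blood_spectrum(ad0: ADSpectrum, ad1: ADSpectrum) -> np.ndarray:
    """Blood-volume difference spectrum A_D,blood = A_D0 − A_D1.

    A_D0 is measured with the forearm at heart level, A_D1 after elevating
    it (which drains blood from the skin); the difference isolates the
    spectral effect of the blood-volume change.
    """
    _check_compatible(ad0, ad1)
    return ad0.ad - ad1.ad


def average_repeats(
    spectra: Sequence[np.ndarray], wavelengths: np.ndarray | None = None
) -> BloodSpectrum:
    """Mean and sample SD over repeated blood-spectrum measurements."""
    if len(spectra) == 0:
        raise ValueError("no repeats to average")
    arr = np.asarray(spectra, dtype=float)
    if arr.ndim != 2:
        raise GridMismatchError("repeats must share one wavelength grid")
    mean = arr.mean(axis=0)
    # sample (n-1) SD; a single repeat has undefined spread, reported as 0
    std = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros_like(mean)
    if wavelengths is None:
        wavelengths = np.arange(arr.shape[1], dtype=float)
    return BloodSpectrum(
        wavelengths=np.asarray(wavelengths, dtype=float),
        mean_ad_blood=mean,
        std_ad_blood=std,
        n_repeats=arr.shape[0],
    )


def glucose_equivalent(
    delta_ad: np.ndarray,
    glucose_sensitivity: np.ndarray,
    wavelengths: np.ndarray,
    at: float,
) -> float:
    """Glucose change (mmol/L) producing the same A_D change at one band.

    Divides an observed A_D change by the per-wavelength sensitivity
    (a.u. per mmol/L); used to express blood-flow artefacts in glucose
    units (e.g. "raising the arm looks like a 1–2 mmol/L change").
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    d = float(np.interp(at, wavelengths, np.asarray(delta_ad, dtype=float)))
    s = float(np.interp(at, wavelengths, np.asarray(glucose_sensitivity, dtype=float)))
    if at < wavelengths.min() or at > wavelengths.max():
        raise GridMismatchError(f"{at} nm outside the sensitivity grid")
    if s == 0:
        raise ZeroDivisionError("glucose sensitivity is zero at the query wavelength")
    return d / s


def spectral_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two spectra across wavelengths, in [−1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise GridMismatchError("need two spectra on one grid with >= 2 points")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("similarity undefined for a zero-variance spectrum")
    return float(np.corrcoef(a, b)[0, 1])
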