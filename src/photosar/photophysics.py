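"""Comparative-method quantum yields.

Singlet-oxygen quantum yields (Phi_Delta) are measured against a
reference dye of known yield by following the photobleaching of the
chemical trap DPBF at 415 nm.  The first-order bleach rate k is the
slope of ln(A0/At) versus irradiation time, and the comparison
corrects for the light actually absorbed by each dye, summed
per-wavelength over the irradiation window (523-850 nm by default,
0.5 nm step) via Beer-Lambert:

    I_a(lambda) = I_0(lambda) * (1 - e^(-2.3 A(lambda)))
    Phi_Delta^S = Phi_Delta^R * (k^S I_aT^R) / (k^R I_aT^S)

Fluorescence quantum yields use the standard comparative formula with
the integrated emission area F, the absorbance A at the excitation
wavelength, and a refractive-index correction:

    Phi_F^S = Phi_F^R * (F^S/F^R) * (1-10^-A^R)/(1-10^-A^S) * (eta^S/eta^R)^2

The absorbed-light exponent uses the constant 2.3 rather than ln 10,
reproducing the stated computation; ``use_ln10=True`` switches to the
exact conversion.  Yields above 1 are flagged, never clamped: they
signal an input or forward-model error and should stay visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .spectra import Spectrum, _uniform_grid

__all__ = [
    "PhotobleachSeries",
    "AbsorbedLight",
    "QuantumYieldResult",
    "SolventInfo",
    "bleach_slope",
    "absorbed_light",
    "singlet_oxygen_qy",
    "fluorescence_qy",
    "REFRACTIVE_INDEX",
]

# refractive indices (sodium D line, 20-25 C) of the solvents used for
# quantum-yield work in this pipeline
REFRACTIVE_INDEX = {
    "DMF": 1.4305,
    "THF": 1.4050,
    "DMSO": 1.4793,
    "water": 1.3330,
    "PBS": 1.3340,
    "ethanol": 1.3611,
    "methanol": 1.3288,
    "toluene": 1.4961,
}


@dataclass(frozen=True)
class SolventInfo:
    """Solvent name plus refractive index eta."""

    name: str
    refractive_index: float

    def __post_init__(self) -> None:
        if not (1.2 <= self.refractive_index <= 1.7):
            raise ValueError(
                f"refractive index {self.refractive_index} outside the "
                "supported range [1.2, 1.7]"
            )

    @classmethod
    def from_name(cls, name: str) -> "SolventInfo":
        try:
            return cls(name, REFRACTIVE_INDEX[name])
        except KeyError:
            raise KeyError(
                f"unknown solvent {name!r}; supply the refractive index explicitly"
            ) from None


@dataclass(frozen=True)
class PhotobleachSeries:
    """DPBF absorbance at 415 nm versus irradiation time."""

    times_s: np.ndarray
    absorbance_415: np.ndarray
    label: str = "sample"  # or "reference"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        a = np.asarray(self.absorbance_415, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "absorbance_415", a)
        if t.size != a.size:
            raise ValueError("times and absorbances must have equal length")
        if t.size < 3:
            raise ValueError("a photobleach series needs at least 3 points")
        if np.any(np.diff(t) <= 0) or t[0] < 0:
            raise ValueError("times must be increasing and nonnegative")
        if np.any(a <= 0):
            raise ValueError("all absorbances must be positive")
        if self.label not in ("sample", "reference"):
            raise ValueError("label must be 'sample' or 'reference'")


@dataclass
class AbsorbedLight:
    """Per-wavelength absorbed light and its total I_aT."""

    wavelengths_nm: np.ndarray
    I_a: np.ndarray
    total_IaT: float


@dataclass
class QuantumYieldResult:
    phi: float
    kind: str  # "singlet_oxygen" | "fluorescence"
    estimated_rel_error: float
    slope_sample: Optional[float] = None
    slope_reference: Optional[float] = None
    IaT_sample: Optional[float] = None
    IaT_reference: Optional[float] = None
    flags: Tuple[str, ...] = field(default_factory=tuple)


def bleach_slope(series: PhotobleachSeries, force_zero_intercept: bool = False) -> float:
    """First-order DPBF bleach rate k (s^-1).

    Ordinary least squares of ln(A0/At) on irradiation time.  The
    intercept is free by default (robust to an error in the initial
    absorbance reading); ``force_zero_intercept=True`` pins the line
    through the origin, matching the raw definition ln(A0/A0) = 0 at
    t = 0.  A negative slope (DPBF growing) is returned but flagged by
    warning.
    """
    t = series.times_s
    y = np.log(series.absorbance_415[0] / series.absorbance_415)
    if force_zero_intercept:
        k = float(np.dot(t, y) / np.dot(t, t))
    else:
        k = float(np.polyfit(t, y, 1)[0])
    if k < 0:
        warnings.warn(f"negative bleach slope k = {k:.3g} s^-1", stacklevel=2)
    return k


def absorbed_light(
    abs_spec: Spectrum,
    excitation_profile: Spectrum,
    lambda_min_nm: float = 523.0,
    lambda_max_nm: float = 850.0,
    step_nm: float = 0.5,
    use_ln10: bool = False,
) -> AbsorbedLight:
    """Total light absorbed by the dye over the irradiation window.

    Both spectra are regridded to a uniform ``step_nm`` grid over
    [lambda_min, lambda_max]; negative post-baseline absorbances are
    clipped to zero here (absorbed light cannot be negative), although
    they are preserved everywhere else in the pipeline.  The profile
    units cancel in the comparative ratio, so either a dimensionless
    filter transmittance or a lamp-weighted profile works.
    """
    if abs_spec.kind != "absorption":
        raise ValueError("abs_spec must be an absorption spectrum")
    grid = _uniform_grid(lambda_min_nm, lambda_max_nm, step_nm)
    try:
        A = abs_spec.interp(grid)
        I0 = excitation_profile.interp(grid)
    except ValueError as exc:
        raise ValueError(f"spectra do not cover the integration window: {exc}") from exc
    if np.any(I0 < 0):
        raise ValueError("excitation profile must be nonnegative")
    A = np.clip(A, 0.0, None)
    coef = np.log(10.0) if use_ln10 else 2.3
    Ia = I0 * (1.0 - np.exp(-coef * A))
    return AbsorbedLight(wavelengths_nm=grid, I_a=Ia, total_IaT=float(Ia.sum()))


def singlet_oxygen_qy(
    k_S: float,
    k_R: float,
    IaT_S: float,
    IaT_R: float,
    phi_R: float,
    replicate_phis: Optional[Sequence[float]] = None,
) -> QuantumYieldResult:
    """Comparative singlet-oxygen quantum yield Phi_Delta.

    Phi^S = Phi^R * (k^S I_aT^R) / (k^R I_aT^S).  The blanket +-10%
    relative error of the comparative method is reported unless >= 3
    replicate yields are given, in which case their sample SD (as a
    relative error) replaces it.
    """
    if k_R <= 0:
        raise ValueError("reference bleach slope must be positive")
    if IaT_S <= 0 or IaT_R <= 0:
        raise ValueError("absorbed-light totals must be positive")
    if not (0 < phi_R <= 1):
        raise ValueError("reference yield must be in (0, 1]")
    phi = phi_R * (k_S * IaT_R) / (k_R * IaT_S)
    flags: list[str] = []
    if phi > 1:
        flags.append("phi_gt_1")
    if k_S < 0:
        flags.append("negative_sample_slope")
    rel = 0.10
    if replicate_phis is not None and len(replicate_phis) >= 3:
        rel = float(np.std(replicate_phis, ddof=1) / np.mean(replicate_phis))
    return QuantumYieldResult(
        phi=float(phi),
        kind="singlet_oxygen",
        estimated_rel_error=rel,
        slope_sample=k_S,
        slope_reference=k_R,
        IaT_sample=IaT_S,
        IaT_reference=IaT_R,
        flags=tuple(flags),
    )


def fluorescence_qy(
    F_S: float,
    F_R: float,
    A_S: float,
    A_R: float,
    solvent_S: SolventInfo,
    solvent_R: SolventInfo,
    phi_R: float,
    replicate_phis: Optional[Sequence[float]] = None,
) -> QuantumYieldResult:
    """Comparative fluorescence quantum yield Phi_F.

    Phi^S = Phi^R (F^S/F^R) (1-10^-A^R)/(1-10^-A^S) (eta^S/eta^R)^2,
    with F the integrated emission area and A the absorbance at the
    excitation wavelength.  Absorbance above 0.05 risks inner-filter
    distortion and is warned about.
    """
    if F_R <= 0:
        raise ValueError("reference emission area must be positive")
    if F_S < 0:
        raise ValueError("sample emission area must be nonnegative")
    if A_S <= 0 or A_R <= 0:
        raise ValueError("excitation absorbances must be positive (no absorbed light)")
    if A_S >= 1 or A_R >= 1:
        raise ValueError("excitation absorbance >= 1 is outside the dilute regime")
    if not (0 < phi_R <= 1):
        raise ValueError("reference yield must be in (0, 1]")
    flags: list[str] = []
    if A_S > 0.05 or A_R > 0.05:
        warnings.warn(
            "excitation absorbance exceeds 0.05; inner-filter effects likely",
            stacklevel=2,
        )
        flags.append("inner_filter_risk")
    phi = (
        phi_R
        * (F_S / F_R)
        * (1.0 - 10.0 ** (-A_R))
        / (1.0 - 10.0 ** (-A_S))
        * (solvent_S.refractive_index / solvent_R.refractive_index) ** 2
    )
    if phi > 1:
        flags.append("phi_gt_1")
    rel = 0.15
    if replicate_phis is not None and len(replicate_phis) >= 3:
        rel = float(np.std(replicate_phis, ddof=1) / np.mean(replicate_phis))
    return QuantumYieldResult(
        phi=float(phi),
        kind="fluorescence",
        estimated_rel_error=rel,
        flags=tuple(flags),
    )
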