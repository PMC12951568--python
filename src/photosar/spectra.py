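"""Spectral preprocessing and Q-band feature extraction.

The :class:`Spectrum` container is the universal currency of the
pipeline: absorption spectra (absorbance, AU), fluorescence emission
spectra (counts, arbitrary units) and filter/lamp transmittance
profiles (dimensionless, in [0, 1]) all travel through it.

Phthalocyanine absorption spectra are dominated by the low-energy
Q-band (~660-760 nm).  A sharp single band indicates monomeric dye;
H-aggregation broadens the band and grows a blue-shifted aggregate
band, which quenches the excited states.  The feature extractor here
reports the Q-band maxima (one or two, for split bands of
low-symmetry macrocycles), the molar extinction coefficient via
Beer-Lambert, the band width, and an aggregation index.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks, peak_widths

__all__ = [
    "Spectrum",
    "QBandFeatures",
    "preprocess",
    "q_band_features",
    "integrate_emission",
    "stokes_shift",
]

_KINDS = ("absorption", "emission", "transmittance")


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed intensity record.

    Parameters
    ----------
    kind
        One of ``"absorption"`` (absorbance, AU), ``"emission"``
        (counts / arbitrary units) or ``"transmittance"``
        (dimensionless, values in [0, 1]).
    wavelengths_nm
        Strictly increasing wavelengths in nanometres.
    values
        Intensities, same length as ``wavelengths_nm``.
    solvent
        Solvent name (free text); refractive-index lookups live in
        :mod:`photosar.photophysics`.
    concentration_M
        Molar dye concentration, if known (used for extinction
        coefficients).
    pathlength_cm
        Optical path length; 1.0 cm cuvettes are the default.
    excitation_nm
        Excitation wavelength; required for emission spectra.
    """

    kind: str
    wavelengths_nm: np.ndarray
    values: np.ndarray
    solvent: str = ""
    concentration_M: Optional[float] = None
    pathlength_cm: float = 1.0
    excitation_nm: Optional[float] = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if self.kind not in _KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise ValueError("spectrum values must be finite")
        if self.kind == "transmittance" and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("transmittance values must lie in [0, 1]")
        if self.kind == "emission" and self.excitation_nm is None:
            raise ValueError("emission spectra require excitation_nm")
        if self.concentration_M is not None and self.concentration_M < 0:
            raise ValueError("concentration_M must be nonnegative")
        if self.pathlength_cm <= 0:
            raise ValueError("pathlength_cm must be positive")

    @property
    def range_nm(self) -> Tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def interp(self, grid_nm: np.ndarray) -> np.ndarray:
        """Linear interpolation of the values onto ``grid_nm``."""
        grid = np.asarray(grid_nm, dtype=float)
        lo, hi = self.range_nm
        if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
            raise ValueError(
                f"grid [{grid.min():g}, {grid.max():g}] nm exceeds spectrum "
                f"range [{lo:g}, {hi:g}] nm"
            )
        return np.interp(grid, self.wavelengths_nm, self.values)

    def scaled(self, factor: float) -> "Spectrum":
        return replace(self, values=self.values * factor)


@dataclass
class QBandFeatures:
    """Q-band descriptors extracted from an absorption spectrum."""

    maxima_nm: Tuple[float, ...]
    absorbance_at_maxima: Tuple[float, ...]
    split: bool
    fwhm_nm: float
    epsilon_M1cm1: Optional[float] = None
    aggregation_index: Optional[float] = None
    flags: Tuple[str, ...] = field(default_factory=tuple)

    @property
    def lambda_max_nm(self) -> float:
        """Primary (highest-absorbance) maximum."""
        return self.maxima_nm[0]


def _uniform_grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(math.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def preprocess(raw: Spectrum, baseline: Spectrum, grid_step_nm: float = 0.5) -> Spectrum:
    """Baseline-subtract and resample a spectrum to a uniform grid.

    The solvent baseline is interpolated onto a uniform grid of step
    ``grid_step_nm`` covering the overlap of the two wavelength ranges
    and subtracted point-wise; wavelengths outside the overlap are
    dropped.
    """
    if raw.kind != baseline.kind:
        raise ValueError(
            f"kind mismatch: raw is {raw.kind!r}, baseline is {baseline.kind!r}"
        )
    if grid_step_nm <= 0:
        raise ValueError("grid_step_nm must be positive")
    lo = max(raw.range_nm[0], baseline.range_nm[0])
    hi = min(raw.range_nm[1], baseline.range_nm[1])
    if hi <= lo:
        raise ValueError("raw and baseline wavelength ranges do not overlap")
    grid = _uniform_grid(lo, hi, grid_step_nm)
    corrected = raw.interp(grid) - baseline.interp(grid)
    return replace(raw, wavelengths_nm=grid, values=corrected)


def q_band_features(
    spec: Spectrum,
    window_nm: Tuple[float, float] = (550.0, 800.0),
    prominence_frac: float = 0.2,
    min_separation_nm: float = 5.0,
    monomer_reference: Optional[Spectrum] = None,
    monomer_fwhm_nm: float = 18.0,
) -> QBandFeatures:
    """Locate the Q-band maxima and derived quantities.

    Local maxima inside ``window_nm`` are detected and up to two are
    retained, requiring a prominence of at least
    ``prominence_frac`` x (window maximum) and a mutual separation of
    at least ``min_separation_nm``; two retained maxima mark a split
    Q-band.  The extinction coefficient follows Beer-Lambert from the
    global window maximum when the concentration is known (for split
    bands this choice is flagged, since either maximum could have been
    used).

    The aggregation index is 1 - A(lambda_mono)/A_ref(lambda_mono)
    against a concentration-matched monomer reference spectrum; with
    no reference a band-width proxy (1 - monomer FWHM / observed FWHM)
    is used and flagged.
    """
    if spec.kind != "absorption":
        raise ValueError("q_band_features requires an absorption spectrum")
    lo, hi = window_nm
    s_lo, s_hi = spec.range_nm
    if lo < s_lo or hi > s_hi or hi <= lo:
        raise ValueError("window must lie inside the spectrum range")
    mask = (spec.wavelengths_nm >= lo) & (spec.wavelengths_nm <= hi)
    wl = spec.wavelengths_nm[mask]
    vals = spec.values[mask]
    vmax = vals.max()
    if vmax <= 0 or np.ptp(vals) < 1e-12 * max(1.0, abs(vmax)):
        raise ValueError("no Q-band: spectrum is flat in the search window")

    idx, props = find_peaks(vals, prominence=prominence_frac * vmax)
    flags: list[str] = []
    if idx.size == 0:
        # the band maximum may sit on the window edge
        idx = np.array([int(np.argmax(vals))])
        props = {"prominences": np.array([vmax])}
        flags.append("maximum_on_window_edge")
    order = np.lexsort((wl[idx], vals[idx]))[::-1]  # by height, ties -> longer wl
    idx = idx[order]
    kept: list[int] = [int(idx[0])]
    for j in idx[1:]:
        if abs(wl[j] - wl[kept[0]]) >= min_separation_nm:
            kept.append(int(j))
            break
    maxima = tuple(float(wl[j]) for j in kept)
    heights = tuple(float(vals[j]) for j in kept)
    split = len(kept) == 2

    widths = peak_widths(vals, np.array(kept[:1]), rel_height=0.5)[0]
    step = float(np.median(np.diff(wl)))
    fwhm = float(widths[0] * step)

    epsilon = None
    if spec.concentration_M:
        epsilon = heights[0] / (spec.concentration_M * spec.pathlength_cm)
        if split:
            flags.append("epsilon_from_global_maximum_of_split_band")

    agg = None
    if monomer_reference is not None:
        ref_vals = monomer_reference.values
        ref_wl = monomer_reference.wavelengths_nm
        rmask = (ref_wl >= lo) & (ref_wl <= hi)
        j = int(np.argmax(ref_vals[rmask]))
        lam_mono = float(ref_wl[rmask][j])
        a_ref = float(ref_vals[rmask][j])
        # match concentrations if both known
        if spec.concentration_M and monomer_reference.concentration_M:
            a_ref *= spec.concentration_M / monomer_reference.concentration_M
        a_here = float(np.interp(lam_mono, wl, vals))
        agg = float(np.clip(1.0 - a_here / a_ref, 0.0, 1.0))
    elif monomer_fwhm_nm:
        agg = float(np.clip(1.0 - monomer_fwhm_nm / fwhm, 0.0, 1.0))
        flags.append("aggregation_index_from_fwhm_proxy")

    return QBandFeatures(
        maxima_nm=maxima,
        absorbance_at_maxima=heights,
        split=split,
        fwhm_nm=fwhm,
        epsilon_M1cm1=epsilon,
        aggregation_index=agg,
        flags=tuple(flags),
    )


def integrate_emission(spec: Spectrum, range_nm: Optional[Tuple[float, float]] = None) -> float:
    """Trapezoidal area under an emission spectrum over ``range_nm``.

    With ``range_nm=None`` the full recorded range is integrated.
    """
    if spec.kind != "emission":
        raise ValueError("integrate_emission requires an emission spectrum")
    if range_nm is None:
        lo, hi = spec.range_nm
    else:
        lo, hi = range_nm
    s_lo, s_hi = spec.range_nm
    if hi <= lo:
        raise ValueError("empty integration range")
    if lo < s_lo - 1e-9 or hi > s_hi + 1e-9:
        raise ValueError("integration range exceeds the recorded spectrum")
    wl = spec.wavelengths_nm
    inner = (wl > lo) & (wl < hi)
    grid = np.concatenate(([lo], wl[inner], [hi]))
    vals = np.interp(grid, wl, spec.values)
    return float(np.trapezoid(vals, grid))


def stokes_shift(lambda_A_nm: float, lambda_F_nm: float) -> float:
    """Stokes shift lambda_F - lambda_A in nm (~10 nm for monomeric Pcs).

    A negative shift is physically suspect (emission blue of
    absorption) and triggers a warning, but is returned as-is.
    """
    if lambda_A_nm <= 0 or lambda_F_nm <= 0:
        raise ValueError("wavelengths must be positive")
    shift = lambda_F_nm - lambda_A_nm
    if shift < 0:
        warnings.warn(
            f"negative Stokes shift ({shift:g} nm): emission maximum blue of "
            "absorption maximum",
            stacklevel=2,
        )
    return shift
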